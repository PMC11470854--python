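"""Composition-based numeric descriptors of protein sequences.

Six encoders map a sequence of N residues onto fixed-length vectors:

========  ====  =========================================================
scheme    dims  definition
========  ====  =========================================================
AAC         20  residue frequencies, f_i / N
DPC        400  overlapping dipeptide frequencies, M_j / (N - 1)
GAAC         5  frequencies of 5 physicochemical residue groups, N(g) / N
GDPC        25  group-pair dipeptide frequencies, N_rs / (N - 1)
CTDC        39  per-attribute 3-class composition, N(r) / N, 13 attributes
CTDT        39  per-attribute class-transition frequencies,
                (N(r,s) + N(s,r)) / (N - 1), 3 unordered pairs
========  ====  =========================================================

AAC, DPC, GAAC and GDPC each sum to 1; CTDC sums to 1 per attribute
(13 overall); CTDT sums to at most 1 per attribute. Column orders are
fixed (alphabetical residues/dipeptides, g1..g5 row-major, attribute-
major for CTD) so feature matrices are bit-comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_ALPHABET, LabeledDataset, SequenceRecord

SCHEMES = ("AAC", "DPC", "GDPC", "GAAC", "CTDC", "CTDT")

#: scheme -> dimensionality of its feature space
SCHEME_DIMS = {"AAC": 20, "DPC": 400, "GDPC": 25, "GAAC": 5, "CTDC": 39, "CTDT": 39}

#: Five physicochemical residue groups: aliphatic, aromatic, positively
#: charged, negatively charged, uncharged.
GAAC_GROUPS: dict[str, str] = {
    "g1": "GAVLMI",
    "g2": "FYW",
    "g3": "KRH",
    "g4": "DE",
    "g5": "STCPNQ",
}

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_ALPHABET)}


@dataclass(frozen=True)
class CTDProperty:
    """One physicochemical attribute: a 3-class partition of the alphabet."""

    name: str
    class_names: tuple[str, str, str]
    class_residues: tuple[str, str, str]


@lru_cache(maxsize=1)
def ctd_properties() -> tuple[CTDProperty, ...]:
    """Load the packaged 13-attribute, 3-class grouping table."""
    text = (
        resources.files("patatinpred").joinpath("data/ctd_groups.tsv").read_text()
    )
    props = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, n1, r1, n2, r2, n3, r3 = line.split("\t")
        props.append(CTDProperty(name, (n1, n2, n3), (r1, r2, r3)))
    if len(props) != 13:
        raise RuntimeError("grouping table must define exactly 13 attributes")
    for p in props:
        combined = "".join(p.class_residues)
        if sorted(combined) != sorted(STANDARD_ALPHABET):
            raise RuntimeError(f"attribute {p.name}: not a partition of the alphabet")
    return tuple(props)


def _codes(seq: SequenceRecord | str) -> np.ndarray:
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    try:
        return np.array([_AA_INDEX[c] for c in s], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside the 20-letter alphabet")


def _require_length(codes: np.ndarray, minimum: int) -> None:
    if codes.size < minimum:
        raise ValueError(
            f"sequence too short ({codes.size} residues, need >= {minimum})"
        )


def aac_names() -> list[str]:
    return list(STANDARD_ALPHABET)


def dpc_names() -> list[str]:
    return [a + b for a in STANDARD_ALPHABET for b in STANDARD_ALPHABET]


def gaac_names() -> list[str]:
    return list(GAAC_GROUPS)


def gdpc_names() -> list[str]:
    groups = list(GAAC_GROUPS)
    return [f"{r}.{s}" for r in groups for s in groups]


def ctdc_names() -> list[str]:
    return [
        f"{p.name}.{cls}" for p in ctd_properties() for cls in p.class_names
    ]


def ctdt_names() -> list[str]:
    names = []
    for p in ctd_properties():
        c1, c2, c3 = p.class_names
        names += [f"{p.name}.{c1}-{c2}", f"{p.name}.{c2}-{c3}", f"{p.name}.{c1}-{c3}"]
    return names


def encode_aac(seq: SequenceRecord | str) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    codes = _codes(seq)
    _require_length(codes, 1)
    return np.bincount(codes, minlength=20) / codes.size


def encode_dpc(seq: SequenceRecord | str) -> np.ndarray:
    """Dipeptide composition: 400 overlapping 2-mer frequencies."""
    codes = _codes(seq)
    _require_length(codes, 2)
    pair_codes = codes[:-1] * 20 + codes[1:]
    return np.bincount(pair_codes, minlength=400) / (codes.size - 1)


@lru_cache(maxsize=1)
def _gaac_map() -> np.ndarray:
    mapping = np.empty(20, dtype=np.intp)
    for gi, residues in enumerate(GAAC_GROUPS.values()):
        for aa in residues:
            mapping[_AA_INDEX[aa]] = gi
    return mapping


def encode_gaac(seq: SequenceRecord | str) -> np.ndarray:
    """Grouped amino-acid composition over 5 physicochemical groups."""
    codes = _codes(seq)
    _require_length(codes, 1)
    groups = _gaac_map()[codes]
    return np.bincount(groups, minlength=5) / codes.size


def encode_gdpc(seq: SequenceRecord | str) -> np.ndarray:
    """Grouped dipeptide composition over ordered 5x5 group pairs."""
    codes = _codes(seq)
    _require_length(codes, 2)
    groups = _gaac_map()[codes]
    pair_codes = groups[:-1] * 5 + groups[1:]
    return np.bincount(pair_codes, minlength=25) / (codes.size - 1)


@lru_cache(maxsize=1)
def _ctd_maps() -> np.ndarray:
    # 13 x 20 matrix of class indices (0/1/2) per attribute per residue
    maps = np.empty((13, 20), dtype=np.intp)
    for pi, prop in enumerate(ctd_properties()):
        for ci, residues in enumerate(prop.class_residues):
            for aa in residues:
                maps[pi, _AA_INDEX[aa]] = ci
    return maps


def encode_ctdc(seq: SequenceRecord | str) -> np.ndarray:
    """CTD composition: class frequencies for each of 13 attributes."""
    codes = _codes(seq)
    _require_length(codes, 1)
    out = np.empty(39)
    for pi in range(13):
        classes = _ctd_maps()[pi][codes]
        out[3 * pi : 3 * pi + 3] = np.bincount(classes, minlength=3) / codes.size
    return out


def encode_ctdt(seq: SequenceRecord | str) -> np.ndarray:
    """CTD transition: adjacent class-change frequencies per attribute.

    For each attribute with classes (1, 2, 3), the three unordered pairs
    are reported in the order 1-2, 2-3, 1-3; a pair (r, s) counts
    adjacent residue pairs encoded r,s or s,r, divided by N - 1.
    """
    codes = _codes(seq)
    _require_length(codes, 2)
    out = np.empty(39)
    for pi in range(13):
        classes = _ctd_maps()[pi][codes]
        a, b = classes[:-1], classes[1:]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        n12 = int(np.sum((lo == 0) & (hi == 1)))
        n23 = int(np.sum((lo == 1) & (hi == 2)))
        n13 = int(np.sum((lo == 0) & (hi == 2)))
        out[3 * pi : 3 * pi + 3] = np.array([n12, n23, n13]) / (codes.size - 1)
    return out


_ENCODERS = {
    "AAC": (encode_aac, aac_names),
    "DPC": (encode_dpc, dpc_names),
    "GDPC": (encode_gdpc, gdpc_names),
    "GAAC": (encode_gaac, gaac_names),
    "CTDC": (encode_ctdc, ctdc_names),
    "CTDT": (encode_ctdt, ctdt_names),
}


def encode_sequence(seq: SequenceRecord | str, scheme: str) -> pd.Series:
    """Encode one sequence under a scheme; returns a named Series."""
    encode, names = _ENCODERS[scheme.upper()]
    return pd.Series(encode(seq), index=names(), name=getattr(seq, "id", None))


def feature_names(scheme: str) -> list[str]:
    return _ENCODERS[scheme.upper()][1]()


def encode_dataset(dataset: LabeledDataset, scheme: str) -> pd.DataFrame:
    """Encode every sequence; rows follow dataset order, plus a `label` column.

    Per-sequence failures are re-raised with the offending record id.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    encode, names = _ENCODERS[scheme.upper()]
    rows = np.empty((len(dataset), SCHEME_DIMS[scheme.upper()]))
    for i, rec in enumerate(dataset):
        try:
            rows[i] = encode(rec)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    matrix = pd.DataFrame(rows, index=[r.id for r in dataset], columns=names())
    matrix["label"] = [r.label for r in dataset]
    return matrix


def matrix_xy(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature matrix into (X, y) with y = 1 for the positive class."""
    X = matrix.drop(columns="label").to_numpy()
    y = (matrix["label"] == "positive").to_numpy().astype(int)
    return X, y
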