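"""Peptide feature extraction: conical residue coordinates, composition and codes.

A peptide chain is turned into two inputs for the classifier:

* a *biological feature* of 660 values — 240 residue-conical-coordinate (RCC)
  moment features, 20 amino-acid composition (AAC) frequencies and 400
  dipeptide composition (DPC) frequencies — viewed as a 33 x 20 map, and
* a *sequence code* of 50 integer tokens (0 = padding, 1-20 = residues in
  alphabetical order) that a learnable embedding consumes.

The RCC feature maps each residue onto a cone determined by its polarity
class: the polar angle ``phi`` is shared by all residues of a class, the
azimuth ``theta`` separates residues within a class by how far their summed
physicochemical properties deviate from the class mean, and the radius is
the residue's molecular weight. Per 10-property group, the geometric centers
of the four classes plus the overall center and per-axis variance/skewness/
kurtosis of the class centers give 24 values; ten groups give 240.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    AA_TO_INDEX,
    AMINO_ACIDS,
    CLASS_OF,
    MAX_PEPTIDE_LENGTH,
    MOLECULAR_WEIGHT,
    NON_CANONICAL,
    RESIDUE_CLASSES,
)

__all__ = [
    "Peptide",
    "PropertyTable",
    "ConicalParams",
    "BioFeature",
    "SequenceError",
    "classify_residue",
    "standardize_properties",
    "load_default_properties",
    "conical_params",
    "conical_map",
    "geometric_centers",
    "moment_features",
    "rcc_feature",
    "aac",
    "dpc",
    "build_bio_feature",
    "encode_sequence",
    "featurize_peptides",
    "FEATURE_NAMES",
]

RCC_DIM = 240
AAC_DIM = 20
DPC_DIM = 400
BIO_DIM = RCC_DIM + AAC_DIM + DPC_DIM  # 660, reshaped 33 x 20
BIO_SHAPE = (33, 20)
CODE_LEN = MAX_PEPTIDE_LENGTH

_MW = np.array([MOLECULAR_WEIGHT[a] for a in AMINO_ACIDS])
_CLASS = np.array([CLASS_OF[a] for a in AMINO_ACIDS])


class SequenceError(ValueError):
    """Raised for sequences that violate the peptide contract."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid chain with an optional detectability label.

    ``label`` is 1 for a detectable peptide, 0 for an undetectable one and
    None when unknown. Sequences must use the 20 canonical one-letter codes
    and contain at least two residues (the dipeptide composition needs one
    adjacent pair).
    """

    sequence: str
    label: int | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise SequenceError(
                f"peptide {self.id or seq!r}: length {len(seq)} < 2"
            )
        bad = sorted({c for c in seq if c not in AA_TO_INDEX})
        if bad:
            kind = "non-canonical" if set(bad) & NON_CANONICAL else "unknown"
            raise SequenceError(
                f"peptide {self.id or seq!r}: {kind} residue(s) {''.join(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def truncated(self) -> str:
        """The first ``MAX_PEPTIDE_LENGTH`` residues used for all features."""
        return self.sequence[:MAX_PEPTIDE_LENGTH]


def classify_residue(residue: str) -> int:
    """Polarity class of a canonical residue: 1 non-polar, 2 polar, 3 basic, 4 acidic."""
    try:
        return CLASS_OF[residue.upper()]
    except KeyError:
        raise SequenceError(f"not a canonical residue: {residue!r}") from None


@dataclass(frozen=True)
class PropertyTable:
    """Standardized 20 x P physicochemical property matrix.

    Rows follow the alphabetical residue order; each column is z-scored
    across the 20 residues. ``groups`` partitions the first 100 columns
    into 10 disjoint blocks of 10 used by the conical mapping.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    groups: tuple[tuple[int, ...], ...]
    standardized: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != 20:
            raise ValueError(f"expected 20 residue rows, got {v.shape[0]}")
        flat = [i for g in self.groups for i in g]
        if sorted(flat) != list(range(len(flat))) or any(
            len(g) != 10 for g in self.groups
        ):
            raise ValueError("groups must be disjoint blocks of 10 covering 0..99")
        if self.standardized:
            mu = v.mean(axis=0)
            sd = v.std(axis=0)
            if not (np.all(np.abs(mu) < 1e-9) and np.all(np.abs(sd - 1) < 1e-9)):
                raise ValueError("standardized table must have column mean 0, sd 1")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_values(self, g: int) -> np.ndarray:
        """20 x 10 standardized block for property group ``g``."""
        return self.values[:, list(self.groups[g])]


def standardize_properties(
    raw: pd.DataFrame | np.ndarray,
    groups: Sequence[Sequence[int]] | None = None,
) -> PropertyTable:
    """Z-score each property column across the 20 residues.

    ``raw`` is a 20 x P matrix (P >= 100); a DataFrame must be indexed by
    one-letter residue codes (rows are reordered alphabetically), an ndarray
    is assumed already in alphabetical order. Columns with zero variance are
    rejected by name/position. Groups default to consecutive blocks of 10
    over the first 100 columns.
    """
    if isinstance(raw, pd.DataFrame):
        missing = set(AMINO_ACIDS) - set(raw.index.astype(str))
        if missing:
            raise ValueError(f"property table missing residues {sorted(missing)}")
        raw = raw.loc[list(AMINO_ACIDS)]
        columns = tuple(str(c) for c in raw.columns)
        values = raw.to_numpy(dtype=float)
    else:
        values = np.asarray(raw, dtype=float)
        columns = tuple(f"p{i}" for i in range(values.shape[1]))
    if values.shape[0] != 20 or values.shape[1] < 100:
        raise ValueError(f"need a 20 x >=100 matrix, got {values.shape}")
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        names = ", ".join(columns[i] for i in dead[:5])
        raise ValueError(f"zero-variance property column(s): {names}")
    z = (values - values.mean(axis=0)) / sd
    if groups is None:
        groups = [tuple(range(10 * g, 10 * g + 10)) for g in range(10)]
    return PropertyTable(
        values=z,
        columns=columns,
        groups=tuple(tuple(int(i) for i in g) for g in groups),
    )


def load_default_properties() -> PropertyTable:
    """Load and standardize the bundled 20 x 100 property table.

    The packaged table contains 100 RDKit molecular descriptors of the 20
    free amino acids (see ``scripts/make_property_table.py`` in the source
    tree); any 20 x >=100 numeric table can be substituted via
    :func:`standardize_properties`.
    """
    with resources.files("pepcaps.data").joinpath("aa_properties.csv").open() as fh:
        raw = pd.read_csv(fh, index_col=0)
    return standardize_properties(raw)


@dataclass(frozen=True)
class ConicalParams:
    """Angles and radii of the conical mapping for one peptide and one group.

    ``phi`` maps each polarity class present in the peptide to its cone
    angle in [0, pi]; ``theta`` (in [0, 2*pi]) and ``r`` (molecular weight,
    Da) are per truncated residue.
    """

    phi: dict[int, float]
    theta: np.ndarray
    r: np.ndarray
    classes: np.ndarray = field(repr=False, default=None)


def _residue_indices(peptide: Peptide) -> np.ndarray:
    return np.array([AA_TO_INDEX[a] for a in peptide.truncated])


def conical_params(peptide: Peptide, group_values: np.ndarray) -> ConicalParams:
    """Compute the cone angle per class and azimuth per residue for one group.

    ``group_values`` is the 20 x 10 standardized property block. Each
    residue's property sum is the row sum of its 10 group properties; the
    class angle ``phi`` is ``pi * |sin(z_i)|`` where ``z_i`` standardizes the
    class-mean property sum against the spread of the class means, and the
    residue azimuth is ``pi + 2*atan`` of the residue's deviation from its
    class mean scaled by the within-class RMS deviation. Degenerate spreads
    (a single class, or a class of identical residues) fall back to
    ``phi = pi/2`` and ``theta = pi``.
    """
    idx = _residue_indices(peptide)
    sums = group_values.sum(axis=1)[idx]  # per-residue property sum
    classes = _CLASS[idx]
    present = sorted(set(int(c) for c in classes))

    dbar = {i: float(sums[classes == i].mean()) for i in present}
    dvals = np.array([dbar[i] for i in present])
    mu = dvals.mean()
    sigma = float(np.sqrt(((dvals - mu) ** 2).mean()))
    if sigma < 1e-12:
        phi = {i: np.pi / 2 for i in present}
    else:
        phi = {
            i: float(np.pi * np.abs(np.sin((dbar[i] - mu) / sigma))) for i in present
        }

    theta = np.full(len(idx), np.pi)
    for i in present:
        mask = classes == i
        dev = sums[mask] - dbar[i]
        rms = float(np.sqrt((dev**2).mean()))
        if rms > 1e-12:
            theta[mask] = np.pi + 2.0 * np.arctan(dev / rms)

    return ConicalParams(phi=phi, theta=theta, r=_MW[idx], classes=classes)


def conical_map(peptide: Peptide, params: ConicalParams) -> np.ndarray:
    """Map each residue to its 3D point ``r*(sin(phi)cos(theta), sin(phi)sin(theta), cos(phi))``."""
    phi = np.array([params.phi[int(c)] for c in params.classes])
    sin_phi, cos_phi = np.sin(phi), np.cos(phi)
    return np.column_stack(
        [
            params.r * sin_phi * np.cos(params.theta),
            params.r * sin_phi * np.sin(params.theta),
            params.r * cos_phi,
        ]
    )


def geometric_centers(
    coords: np.ndarray, classes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Overall center and the four class centers of the residue point cloud.

    A class with no residues in the peptide gets the overall center (so it
    contributes zero deviation to every moment).
    """
    if len(coords) == 0:
        raise ValueError("empty coordinate set")
    u = coords.mean(axis=0)
    ui = np.tile(u, (4, 1))
    for i in RESIDUE_CLASSES:
        mask = classes == i
        if mask.any():
            ui[i - 1] = coords[mask].mean(axis=0)
    return u, ui


def moment_features(
    u: np.ndarray, ui: np.ndarray, kurtosis_sigma2: bool = False
) -> np.ndarray:
    """Per-axis variance, skewness and kurtosis of the 4 class centers.

    Moments are taken over the four class-center deviations from the overall
    center, per axis. ``kurtosis_sigma2=True`` divides the fourth moment by
    sigma^2 instead of the conventional sigma^4. Axes with zero spread give
    zero skewness and kurtosis.
    """
    dev = ui - u  # 4 x 3
    var = (dev**2).mean(axis=0)
    sigma = np.sqrt(var)
    g = np.zeros(3)
    h = np.zeros(3)
    ok = sigma > 1e-12
    g[ok] = (dev[:, ok] ** 3).mean(axis=0) / sigma[ok] ** 3
    kden = sigma[ok] ** 2 if kurtosis_sigma2 else sigma[ok] ** 4
    h[ok] = (dev[:, ok] ** 4).mean(axis=0) / kden
    return np.concatenate([var, g, h])


def rcc_feature(
    peptide: Peptide, table: PropertyTable, kurtosis_sigma2: bool = False
) -> np.ndarray:
    """240-value residue-conical-coordinate feature: 10 groups x 24 values.

    Per group the block is [4 class centers (12), overall center (3),
    variance/skewness/kurtosis per axis (9)].
    """
    blocks = []
    for g in range(table.n_groups):
        params = conical_params(peptide, table.group_values(g))
        coords = conical_map(peptide, params)
        u, ui = geometric_centers(coords, params.classes)
        blocks.append(
            np.concatenate([ui.ravel(), u, moment_features(u, ui, kurtosis_sigma2)])
        )
    return np.concatenate(blocks)


def aac(peptide: Peptide) -> np.ndarray:
    """Amino-acid composition: frequency of each residue over the chain length."""
    idx = _residue_indices(peptide)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(idx)


def dpc(peptide: Peptide) -> np.ndarray:
    """Dipeptide composition: frequency of each ordered adjacent pair.

    The 400 dipeptides are laid out row-major (first residue major) in
    alphabetical order; counts are normalized by the L-1 adjacent positions
    so the vector sums to one.
    """
    idx = _residue_indices(peptide)
    if len(idx) < 2:
        raise SequenceError("dipeptide composition needs length >= 2")
    pair = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair, minlength=400).astype(float)
    return counts / (len(idx) - 1)


@dataclass(frozen=True)
class BioFeature:
    """The 660-value biological feature of one peptide (RCC ++ AAC ++ DPC)."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        if self.vector.shape != (BIO_DIM,):
            raise ValueError(f"expected {BIO_DIM} values, got {self.vector.shape}")

    @property
    def matrix_view(self) -> np.ndarray:
        """Row-major 33 x 20 view fed to the convolutional branch."""
        return self.vector.reshape(BIO_SHAPE)


def build_bio_feature(
    peptide: Peptide, table: PropertyTable, kurtosis_sigma2: bool = False
) -> BioFeature:
    """Concatenate RCC (240) ++ AAC (20) ++ DPC (400) into the 660-value feature."""
    return BioFeature(
        np.concatenate(
            [rcc_feature(peptide, table, kurtosis_sigma2), aac(peptide), dpc(peptide)]
        )
    )


def encode_sequence(peptide: Peptide, max_len: int = CODE_LEN) -> np.ndarray:
    """Integer sequence code: residues as 1-20 (alphabetical), right-padded with 0.

    Sequences longer than ``max_len`` keep their first ``max_len`` residues.
    """
    idx = np.array([AA_TO_INDEX[a] + 1 for a in peptide.sequence[:max_len]])
    code = np.zeros(max_len, dtype=np.int64)
    code[: len(idx)] = idx
    return code


def _feature_names() -> list[str]:
    names = []
    for g in range(10):
        for c in range(1, 5):
            names += [f"rcc_g{g}_c{c}_{ax}" for ax in "xyz"]
        names += [f"rcc_g{g}_center_{ax}" for ax in "xyz"]
        for stat in ("var", "skew", "kurt"):
            names += [f"rcc_g{g}_{stat}_{ax}" for ax in "xyz"]
    names += [f"aac_{a}" for a in AMINO_ACIDS]
    names += [f"dpc_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())


def featurize_peptides(
    peptides: Sequence[Peptide],
    table: PropertyTable | None = None,
    kurtosis_sigma2: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Featurize a batch: (n, 660) biological features and (n, 50) sequence codes."""
    if table is None:
        table = load_default_properties()
    bio = np.stack(
        [build_bio_feature(p, table, kurtosis_sigma2).vector for p in peptides]
    )
    codes = np.stack([encode_sequence(p) for p in peptides])
    return bio, codes
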