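"""Peptide dataset I/O, split management and seeded synthetic data.

Real detectability corpora (GPMDB-derived sets, neXtProt benchmarks) are not
bundled; :func:`generate_synthetic` plants a seedable detectability rule in
random peptides so the full pipeline is testable offline. The rule couples
the label to signals the feature pipeline can see — the fraction of
non-polar (hydrophobic) residues, the count of the tryptic basic residues
K/R, and chain length — through a logistic latent score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold, train_test_split

from .constants import AMINO_ACIDS, RESIDUE_CLASSES
from .features import Peptide, SequenceError

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "read_peptides",
    "write_fasta",
    "write_table",
    "make_splits",
    "generate_synthetic",
]


@dataclass
class Dataset:
    """An ordered collection of peptides with optional fold assignments."""

    peptides: list[Peptide]
    split_assignment: np.ndarray | None = None  # fold index (or 0 train / 1 test)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides if p.id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate peptide ids in dataset")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def labels(self) -> np.ndarray:
        if any(p.label is None for p in self.peptides):
            raise ValueError("dataset has unlabeled peptides")
        return np.array([p.label for p in self.peptides], dtype=np.int64)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def subset(self, mask: np.ndarray) -> "Dataset":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return Dataset(
            [self.peptides[i] for i in idx],
            provenance={**self.provenance, "subset_of": len(self)},
        )


def _build_peptide(seq: str, label, pid, lineno, policy: str, dropped: list) -> Peptide | None:
    if policy == "drop_residue":
        seq = "".join(c for c in seq.upper() if c in AMINO_ACIDS)
    try:
        lbl = None if label is None or (isinstance(label, float) and np.isnan(label)) else int(label)
        return Peptide(sequence=seq, label=lbl, id=pid)
    except (SequenceError, ValueError) as exc:
        logger.warning("rejected record at line %s: %s", lineno, exc)
        dropped.append((lineno, str(exc)))
        if policy == "reject":
            return None
        return None


def read_peptides(
    path: str | Path,
    labels_path: str | Path | None = None,
    non_canonical: str = "reject",
) -> Dataset:
    """Read peptides from FASTA (+ optional id/label TSV) or a TSV/CSV table.

    Table files need a header with a ``sequence`` column and optional
    ``id``/``label`` columns. ``non_canonical`` is ``"reject"`` (drop the
    record, logged) or ``"drop_residue"`` (strip offending residues).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such input file: {path}")
    if non_canonical not in ("reject", "drop_residue"):
        raise ValueError(f"unknown non-canonical policy {non_canonical!r}")
    dropped: list = []
    peptides: list[Peptide] = []

    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        labels: dict[str, int] = {}
        if labels_path is not None:
            lab = pd.read_csv(labels_path, sep="\t")
            labels = dict(zip(lab["id"].astype(str), lab["label"].astype(int)))
        seen: set[str] = set()
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seen.add(rec.id)
            lbl = labels.get(rec.id)
            if labels and lbl is None:
                raise ValueError(f"FASTA id {rec.id!r} missing from labels file")
            p = _build_peptide(str(rec.seq), lbl, rec.id, i + 1, non_canonical, dropped)
            if p is not None:
                peptides.append(p)
        orphans = set(labels) - seen
        if orphans:
            raise ValueError(f"label id(s) not in FASTA: {sorted(orphans)[:5]}")
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
        if "sequence" not in df.columns:
            raise ValueError(f"{path}: no 'sequence' column (found {list(df.columns)})")
        if df.empty:
            raise ValueError(f"{path}: empty peptide table")
        for i, row in df.iterrows():
            p = _build_peptide(
                str(row["sequence"]),
                row.get("label"),
                str(row["id"]) if "id" in df.columns else None,
                i + 2,
                non_canonical,
                dropped,
            )
            if p is not None:
                peptides.append(p)
    if not peptides:
        raise ValueError(f"{path}: no valid peptide records")
    return Dataset(
        peptides,
        provenance={"source": str(path), "n_rejected": len(dropped)},
    )


def write_fasta(ds: Dataset, fasta_path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write sequences as 60-column wrapped FASTA, labels to a sidecar TSV."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id or f"pep{i}", description="")
        for i, p in enumerate(ds.peptides)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if labels_path is not None:
        pd.DataFrame(
            {"id": [r.id for r in records], "label": [p.label for p in ds.peptides]}
        ).to_csv(labels_path, sep="\t", index=False)


def write_table(ds: Dataset, path: str | Path) -> None:
    """Write an id/sequence/label table (TSV or CSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(
        {
            "id": [p.id or f"pep{i}" for i, p in enumerate(ds.peptides)],
            "sequence": [p.sequence for p in ds.peptides],
            "label": [p.label for p in ds.peptides],
        }
    ).to_csv(path, sep=sep, index=False)


def make_splits(ds: Dataset, scheme: str = "kfold", k: int = 10, test_size: float = 0.25, seed: int = 0) -> Dataset:
    """Assign stratified splits: ``kfold`` fold indices or a 75/25 ``holdout``.

    Holdout marks training records 0 and test records 1. Both schemes are
    stratified by label and deterministic under ``seed``.
    """
    y = ds.labels
    assignment = np.full(len(ds), -1, dtype=np.int64)
    if scheme == "kfold":
        if len(ds) < k:
            raise ValueError(f"cannot make {k} folds from {len(ds)} records")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            assignment[test_idx] = fold
    elif scheme == "holdout":
        idx = np.arange(len(ds))
        _, test_idx = train_test_split(
            idx, test_size=test_size, stratify=y, random_state=seed
        )
        assignment[test_idx] = 1
        assignment[assignment == -1] = 0
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    return Dataset(
        ds.peptides,
        split_assignment=assignment,
        provenance={**ds.provenance, "split": {"scheme": scheme, "k": k, "seed": seed}},
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-rule peptide generator.

    Each peptide draws a hydrophobic propensity from Beta(2, 2) and samples
    residues class-biased by it; the latent detectability score is
    ``logistic(w . [hydrophobic fraction - 0.4, K/R count - 2, L/50 - 0.57] + b)``
    with the intercept ``b`` solved so the mean score matches ``balance``.
    Labels are Bernoulli draws from the score, then flipped at ``noise``.
    Default weights are strong so that, at noise 0, the rule is nearly
    deterministic and pipeline failures — not generator ambiguity — dominate
    test outcomes.
    """

    n: int = 1000
    min_length: int = 7
    max_length: int = 50
    balance: float = 0.5
    w_hydrophobic: float = 64.0
    w_basic: float = 4.0
    w_length: float = 10.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 2 <= self.min_length <= self.max_length:
            raise ValueError("need 2 <= min_length <= max_length")
        if not 0 < self.balance < 1:
            raise ValueError("balance must be in (0, 1)")
        if not 0 <= self.noise <= 0.5:
            raise ValueError("noise must be in [0, 0.5]")


_HYDROPHOBIC = sorted(RESIDUE_CLASSES[1])
_OTHER = sorted(set(AMINO_ACIDS) - RESIDUE_CLASSES[1])


def _latent_features(seq: str) -> np.ndarray:
    L = len(seq)
    f_h = sum(c in RESIDUE_CLASSES[1] for c in seq) / L
    f_b = sum(c in "KR" for c in seq)
    return np.array([f_h - 0.4, f_b - 2.0, L / 50.0 - 0.57])


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Generate a labelled synthetic dataset; same spec + seed is bit-identical."""
    rng = np.random.default_rng(spec.seed)
    seqs: list[str] = []
    for _ in range(spec.n):
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        p_h = rng.beta(2.0, 2.0)
        hydro = rng.random(L) < p_h
        res_h = rng.integers(0, len(_HYDROPHOBIC), L)
        res_o = rng.integers(0, len(_OTHER), L)
        seqs.append(
            "".join(
                _HYDROPHOBIC[res_h[i]] if hydro[i] else _OTHER[res_o[i]]
                for i in range(L)
            )
        )

    w = np.array([spec.w_hydrophobic, spec.w_basic, spec.w_length])
    z = np.array([_latent_features(s) @ w for s in seqs])
    # intercept: bisect so the mean Bernoulli rate hits the balance target
    lo, hi = -50.0, 50.0
    for _ in range(100):
        b = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(z + b)))).mean() > spec.balance:
            hi = b
        else:
            lo = b
    score = 1.0 / (1.0 + np.exp(-(z + 0.5 * (lo + hi))))
    labels = (rng.random(spec.n) < score).astype(np.int64)
    if spec.noise > 0:
        flip = rng.random(spec.n) < spec.noise
        labels[flip] = 1 - labels[flip]

    peptides = [
        Peptide(sequence=s, label=int(l), id=f"syn{i:06d}")
        for i, (s, l) in enumerate(zip(seqs, labels))
    ]
    prov = {"generator": "pepcaps.generate_synthetic", "spec": spec.__dict__.copy()}
    return Dataset(peptides, provenance=prov)


def write_provenance(ds: Dataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ds.provenance, indent=2, default=str) + "\n")
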