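"""Synthetic labelled TCR repertoires for offline development and testing.

The generator reproduces the statistical structure the classifier relies
on, without pretending to be a V(D)J recombination simulator:

* CDR3 lengths follow a rounded Gaussian (mean 14.5, sd 2.0) truncated to
  [10, 24] residues, matching the observation that repertoire length
  distributions are approximately Gaussian with 12-16-mers most common;
* every sequence starts with C and ends with F, uses only the 20-letter
  alphabet, and so passes the default quality filters by construction;
* clone abundances are heavy-tailed (Zipf law over abundance ranks,
  exponent 1.2) and normalised to clone fractions;
* "cancer" bags carry short (3-4 residue) peptide motifs planted into a
  fraction ``f`` (default 0.3) of their instances at uniform interior
  positions; "healthy" bags carry the same motifs at a background rate
  ``f0`` (default 0.02).  Ground-truth per-instance flags are retained.

Cohorts can be written in the same MiXCR-style TSV dialect the reader
consumes, with ground truth as a sidecar JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .repertoire_io import (
    AMINO_ACIDS,
    FilterCriteria,
    RepertoireBag,
    TCRClone,
    build_bag,
    filter_clones,
)

DEFAULT_MOTIFS = ("WQDG", "RLNT", "KHEY")


@dataclass(frozen=True)
class SimConfig:
    n_per_class: int = 100
    clones_per_sample: int = 120
    length_mean: float = 14.5
    length_sd: float = 2.0
    length_range: tuple[int, int] = (10, 24)
    zipf_exponent: float = 1.2
    motif_set: tuple[str, ...] = DEFAULT_MOTIFS
    motif_rate_case: float = 0.3
    motif_rate_control: float = 0.02
    #: log-odds boost for motif-bearing clones to occupy high abundance
    #: ranks, emulating antigen-driven clonal expansion of tumour-reactive
    #: clones; 0 makes motif presence independent of abundance
    expansion_bias: float = 1.5
    background_freqs: tuple[float, ...] | None = None  # uniform when None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_rate_case <= 1.0 and 0.0 <= self.motif_rate_control <= 1.0):
            raise ValueError("motif rates must lie in [0, 1]")
        for m in self.motif_set:
            if any(ch not in AMINO_ACIDS for ch in m):
                raise ValueError(f"motif {m!r} uses characters outside the amino-acid alphabet")
        if self.background_freqs is not None and len(self.background_freqs) != len(AMINO_ACIDS):
            raise ValueError("background_freqs must have one entry per amino acid")


@dataclass
class SyntheticCohort:
    bags: list[RepertoireBag]
    motif_flags: list[np.ndarray]  # per bag, aligned with bag.instances
    config: SimConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags])


def _background(config: SimConfig) -> np.ndarray:
    if config.background_freqs is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    p = np.asarray(config.background_freqs, dtype=float)
    return p / p.sum()


def truncated_length_mean(config: SimConfig) -> float:
    """Exact mean of the rounded, truncated Gaussian length law (an
    independent closed-form summation, useful as a test oracle)."""
    lo, hi = config.length_range
    from scipy.stats import norm

    ls = np.arange(lo, hi + 1)
    # mass of round(N(mu, sd)) == l, renormalised over the admissible range
    w = norm.cdf((ls + 0.5 - config.length_mean) / config.length_sd) - norm.cdf(
        (ls - 0.5 - config.length_mean) / config.length_sd
    )
    w /= w.sum()
    return float((ls * w).sum())


def sample_cdr3(config: SimConfig, rng: np.random.Generator) -> str:
    """One background CDR3: C + interior residues + F, truncated-Gaussian length."""
    lo, hi = config.length_range
    while True:
        L = int(np.rint(rng.normal(config.length_mean, config.length_sd)))
        if lo <= L <= hi:
            break
    p = _background(config)
    interior = rng.choice(list(AMINO_ACIDS), size=L - 2, p=p)
    return "C" + "".join(interior) + "F"


def plant_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Overwrite a uniform interior window of ``seq`` with ``motif``.

    The C/F anchor residues are never touched; the output length equals the
    input length.
    """
    interior = len(seq) - 2
    if len(motif) > interior:
        raise ValueError(f"motif {motif!r} does not fit the interior of a length-{len(seq)} sequence")
    start = 1 + int(rng.integers(0, interior - len(motif) + 1))
    return seq[:start] + motif + seq[start + len(motif) :]


def _zipf_fractions(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def generate_sample(
    config: SimConfig,
    rng: np.random.Generator,
    is_case: bool,
) -> tuple[list[TCRClone], np.ndarray]:
    """Clone table for one sample plus per-clone motif ground truth."""
    n = config.clones_per_sample
    rate = config.motif_rate_case if is_case else config.motif_rate_control
    fractions = _zipf_fractions(n, config.zipf_exponent)
    seqs: list[str] = []
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        seq = sample_cdr3(config, rng)
        if rng.random() < rate:
            motif = config.motif_set[int(rng.integers(0, len(config.motif_set)))]
            seq = plant_motif(seq, motif, rng)
            flags[i] = True
        seqs.append(seq)
    # antigen-driven expansion: motif-bearing clones are favoured for the
    # top abundance ranks (Plackett-Luce via Gumbel-perturbed log-weights)
    keys = config.expansion_bias * flags.astype(float) + rng.gumbel(size=n)
    order = np.argsort(-keys)
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(n)
    clones: list[TCRClone] = []
    for i in range(n):
        seq = seqs[i]
        frac = float(fractions[rank_of[i]])
        clones.append(
            TCRClone(
                cdr3_aa=seq,
                v_gene=f"TRBV{int(rng.integers(1, 31))}-1*00(1250)",
                clone_count=max(1, int(round(frac * 1e5))),
                clone_fraction=frac,
            )
        )
    return clones, flags


def generate_cohort(config: SimConfig, k: int = 100) -> SyntheticCohort:
    """Balanced labelled cohort of case (label 1) and control (label 0) bags.

    Each sample's clones are filtered and ranked exactly as real data would
    be; per-instance ground-truth motif flags are carried through to the bag
    slots.  The same seed always yields the identical cohort.
    """
    if config.motif_rate_case <= config.motif_rate_control:
        warnings.warn(
            "motif rate in cases does not exceed controls; signal may be unlearnable",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    bags: list[RepertoireBag] = []
    all_flags: list[np.ndarray] = []
    for label in (0, 1):
        for i in range(config.n_per_class):
            sample_id = f"{'case' if label else 'ctrl'}_{i:04d}"
            clones, flags = generate_sample(config, rng, is_case=bool(label))
            flag_of = {id(c): bool(fl) for c, fl in zip(clones, flags)}
            survivors, _ = filter_clones(clones, FilterCriteria())
            bag = build_bag(survivors, k=k, sample_id=sample_id, label=label)
            bag_flags = np.array(
                [flag_of.get(id(c), False) if c is not None else False for c in bag.instances]
            )
            bags.append(bag)
            all_flags.append(bag_flags)
    return SyntheticCohort(bags=bags, motif_flags=all_flags, config=config)


# ---------------------------------------------------------------------------
# round-trip with the reader's TSV dialect


def write_cohort_tsv(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """One MiXCR-dialect TSV per sample, a labels table, and ground truth JSON."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels_rows = []
    truth: dict[str, list[bool]] = {}
    for bag, flags in zip(cohort.bags, cohort.motif_flags):
        rows = []
        for clone, real in zip(bag.instances, bag.mask):
            if not real or clone is None:
                continue
            rows.append(
                {
                    "aaSeqCDR3": clone.cdr3_aa,
                    "allVHitsWithScore": clone.v_gene,
                    "cloneCount": clone.clone_count,
                    "cloneFraction": clone.clone_fraction,
                }
            )
        pd.DataFrame(rows).to_csv(out_dir / f"{bag.sample_id}.tsv", sep="\t", index=False)
        labels_rows.append({"sample_id": bag.sample_id, "label": bag.label})
        truth[bag.sample_id] = [bool(f) for f in flags]
    pd.DataFrame(labels_rows).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))
    return out_dir
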