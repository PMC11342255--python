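"""Reading clone tables, CDR3 quality filtering, and bag construction.

A *repertoire* is the set of TCR clonotypes observed in one biological
sample.  The classifier treats each sample as a multiple-instance-learning
"bag" holding the ``k`` most abundant CDR3 amino-acid sequences that survive
quality filtering; this module turns a MiXCR-style clone export into such a
bag.

Filtering keeps a CDR3 only if, in order:

(i)   its variable-gene locus is resolved (unambiguous V annotation),
(ii)  it contains no special characters (``X``, ``*``, ``_``),
(iii) it begins with cysteine (C) and ends with phenylalanine (F),
(iv)  its length lies in [10, 24] residues.

Each rejected clone is attributed to the *first* failing criterion, so the
report mirrors a per-step survival table.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: logical field -> default column name in a MiXCR export
DEFAULT_DIALECT: dict[str, str] = {
    "cdr3_aa": "aaSeqCDR3",
    "v_gene": "allVHitsWithScore",
    "clone_count": "cloneCount",
    "clone_fraction": "cloneFraction",
}

#: filter criteria in the order rejections are attributed
CRITERIA_ORDER = ("unresolved_v", "forbidden_char", "terminal_residues", "length")


class ConfigurationError(ValueError):
    """Raised when a table cannot be mapped onto the expected columns."""


class EmptyRepertoireError(ValueError):
    """Raised when no clone survives filtering and a bag is requested."""


@dataclass(frozen=True)
class TCRClone:
    """A single clonotype: CDR3 amino-acid sequence plus abundance."""

    cdr3_aa: str
    v_gene: str | None = None
    clone_count: int = 0
    clone_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.clone_count < 0:
            raise ValueError("clone_count must be non-negative")
        if self.clone_fraction is not None and not (0.0 <= self.clone_fraction <= 1.0):
            raise ValueError("clone_fraction must lie in [0, 1]")

    @property
    def abundance(self) -> float:
        """Ranking key: clone fraction when present, clone count otherwise."""
        return self.clone_fraction if self.clone_fraction is not None else float(self.clone_count)


@dataclass(frozen=True)
class FilterCriteria:
    min_len: int = 10
    max_len: int = 24
    forbidden_chars: frozenset[str] = frozenset({"X", "*", "_"})
    required_start: str = "C"
    required_end: str = "F"
    require_resolved_v: bool = True
    #: strict: any multi-hit V annotation is unresolved; lenient (default):
    #: a comma-separated hit list with a unique top score still counts.
    v_strict: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.forbidden_chars & {self.required_start, self.required_end}:
            raise ValueError("forbidden characters overlap the required terminals")


@dataclass
class FilterReport:
    """Accounting of one filtering pass: every input clone is either a
    survivor or attributed to exactly one (first-failing) criterion."""

    n_input: int
    n_pass: int
    rejections: dict[str, int]
    length_histogram: dict[int, int]

    def check_conservation(self) -> bool:
        return self.n_pass + sum(self.rejections.values()) == self.n_input

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input": self.n_input,
                    "n_pass": self.n_pass,
                    "rejections": self.rejections,
                    "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
                },
                indent=2,
            )
        )


@dataclass
class RepertoireBag:
    """A sample's ordered top-``k`` clone set (the MIL bag).

    ``instances`` always has length ``k``; slots beyond the available
    survivors hold ``None`` and are marked ``False`` in ``mask``.
    """

    sample_id: str
    label: int
    instances: list[TCRClone | None]
    mask: list[bool]
    k: int

    def __post_init__(self) -> None:
        if len(self.instances) != self.k or len(self.mask) != self.k:
            raise ValueError("instances and mask must both have length k")

    @property
    def n_real(self) -> int:
        return sum(self.mask)

    def real_instances(self) -> list[TCRClone]:
        return [c for c, m in zip(self.instances, self.mask) if m]


# ---------------------------------------------------------------------------
# reading

_HIT_SCORE_RE = re.compile(r"\(([-+0-9.eE]+)\)")


def _parse_count(value) -> int:
    try:
        out = int(float(value))
        return out if out >= 0 else 0
    except (TypeError, ValueError):
        return 0


def _parse_fraction(value) -> float | None:
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return f if 0.0 <= f <= 1.0 else None


def read_repertoire_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[TCRClone]:
    """Parse a tab-separated clone table into :class:`TCRClone` records.

    ``dialect`` remaps logical fields (``cdr3_aa``, ``v_gene``,
    ``clone_count``, ``clone_fraction``) onto column names; unmapped fields
    fall back to the MiXCR export defaults.  Row order is retained and rows
    with unparseable abundance get ``clone_count`` 0.
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning no clones", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path} has no data rows", stacklevel=2)
        return []

    if cols["cdr3_aa"] not in df.columns:
        raise ConfigurationError(
            f"mandatory CDR3 column {cols['cdr3_aa']!r} missing from {path.name}"
        )
    has_count = cols["clone_count"] in df.columns
    has_fraction = cols["clone_fraction"] in df.columns
    if not (has_count or has_fraction):
        raise ConfigurationError(
            f"no abundance column: expected {cols['clone_count']!r} or "
            f"{cols['clone_fraction']!r} in {path.name}"
        )
    has_v = cols["v_gene"] in df.columns

    clones: list[TCRClone] = []
    for _, row in df.iterrows():
        seq = row[cols["cdr3_aa"]]
        if not isinstance(seq, str) or not seq:
            continue
        v = row[cols["v_gene"]] if has_v else None
        if isinstance(v, float):  # NaN from pandas
            v = None
        clones.append(
            TCRClone(
                cdr3_aa=seq,
                v_gene=v,
                clone_count=_parse_count(row[cols["clone_count"]]) if has_count else 0,
                clone_fraction=_parse_fraction(row[cols["clone_fraction"]]) if has_fraction else None,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# filtering


def v_gene_resolved(v_gene: str | None, strict: bool = False) -> bool:
    """Whether a V annotation counts as a resolved variable gene locus.

    A missing/empty annotation is unresolved.  A single hit is resolved.  For
    comma-separated multi-hit annotations: unresolved under ``strict``;
    otherwise resolved iff the per-hit scores (in parentheses, MiXCR style)
    identify a unique top hit.
    """
    if v_gene is None or not v_gene.strip():
        return False
    hits = [h for h in v_gene.split(",") if h.strip()]
    if len(hits) <= 1:
        return True
    if strict:
        return False
    scores = []
    for h in hits:
        m = _HIT_SCORE_RE.search(h)
        if m is None:
            return False
        scores.append(float(m.group(1)))
    top = max(scores)
    return scores.count(top) == 1


def _first_failure(clone: TCRClone, c: FilterCriteria) -> str | None:
    if c.require_resolved_v and not v_gene_resolved(clone.v_gene, c.v_strict):
        return "unresolved_v"
    if any(ch in c.forbidden_chars for ch in clone.cdr3_aa):
        return "forbidden_char"
    if not (clone.cdr3_aa.startswith(c.required_start) and clone.cdr3_aa.endswith(c.required_end)):
        return "terminal_residues"
    if not (c.min_len <= len(clone.cdr3_aa) <= c.max_len):
        return "length"
    return None


def filter_clones(
    clones: Sequence[TCRClone],
    criteria: FilterCriteria | None = None,
) -> tuple[list[TCRClone], FilterReport]:
    """Apply the CDR3 quality criteria; pure and idempotent.

    Returns the surviving clones (input order preserved) and a
    :class:`FilterReport` attributing each rejection to its first failing
    criterion.
    """
    criteria = criteria or FilterCriteria()
    survivors: list[TCRClone] = []
    rejections = {name: 0 for name in CRITERIA_ORDER}
    for clone in clones:
        failure = _first_failure(clone, criteria)
        if failure is None:
            survivors.append(clone)
        else:
            rejections[failure] += 1
    report = FilterReport(
        n_input=len(clones),
        n_pass=len(survivors),
        rejections=rejections,
        length_histogram=length_histogram(survivors),
    )
    return survivors, report


def length_histogram(clones: Iterable[TCRClone]) -> dict[int, int]:
    """CDR3 length -> clone count."""
    return dict(Counter(len(c.cdr3_aa) for c in clones))


# ---------------------------------------------------------------------------
# bag construction


def build_bag(
    survivors: Sequence[TCRClone],
    k: int = 100,
    pad_policy: str = "zero",
    sample_id: str = "",
    label: int = 0,
    dedupe: bool = False,
) -> RepertoireBag:
    """Rank survivors by descending abundance and keep the top ``k``.

    Ties in abundance break by lexicographic CDR3, then input order, so the
    bag is a deterministic function of the survivor multiset.  When fewer
    than ``k`` survivors exist, ``zero`` padding fills the tail with masked
    ``None`` slots while ``resample`` repeats survivors cyclically (all
    real).  ``dedupe`` collapses identical CDR3 sequences before ranking,
    keeping the most abundant record.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if pad_policy not in ("zero", "resample"):
        raise ValueError(f"unknown pad_policy {pad_policy!r}")
    if not survivors:
        raise EmptyRepertoireError("empty repertoire after filtering")

    pool = list(survivors)
    if dedupe:
        best: dict[str, TCRClone] = {}
        for c in pool:
            prev = best.get(c.cdr3_aa)
            if prev is None or c.abundance > prev.abundance:
                best[c.cdr3_aa] = c
        pool = list(best.values())

    ranked = sorted(
        enumerate(pool), key=lambda t: (-t[1].abundance, t[1].cdr3_aa, t[0])
    )
    top = [c for _, c in ranked[:k]]

    if len(top) >= k:
        instances: list[TCRClone | None] = top[:k]
        mask = [True] * k
    elif pad_policy == "zero":
        instances = top + [None] * (k - len(top))
        mask = [True] * len(top) + [False] * (k - len(top))
    else:  # resample
        instances = [top[i % len(top)] for i in range(k)]
        mask = [True] * k
    return RepertoireBag(sample_id=sample_id, label=label, instances=instances, mask=mask, k=k)


def write_bag_manifest(bag: RepertoireBag, path: str | Path) -> None:
    """Bag as TSV: sample_id, rank, cdr3_aa, abundance, masked flag."""
    rows = []
    for rank, (clone, real) in enumerate(zip(bag.instances, bag.mask), start=1):
        rows.append(
            {
                "sample_id": bag.sample_id,
                "rank": rank,
                "cdr3_aa": clone.cdr3_aa if clone is not None else "",
                "abundance": clone.abundance if clone is not None else 0.0,
                "masked": not real,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bag_manifest(path: str | Path, label: int = 0) -> RepertoireBag:
    """Inverse of :func:`write_bag_manifest` (abundance goes to clone_fraction
    when it lies in [0, 1], clone_count otherwise)."""
    df = pd.read_csv(path, sep="\t")
    instances: list[TCRClone | None] = []
    mask: list[bool] = []
    sample_id = ""
    for _, row in df.iterrows():
        sample_id = str(row["sample_id"])
        if bool(row["masked"]):
            instances.append(None)
            mask.append(False)
        else:
            ab = float(row["abundance"])
            if 0.0 <= ab <= 1.0:
                clone = TCRClone(cdr3_aa=row["cdr3_aa"], v_gene="manifest", clone_fraction=ab)
            else:
                clone = TCRClone(cdr3_aa=row["cdr3_aa"], v_gene="manifest", clone_count=int(ab))
            instances.append(clone)
            mask.append(True)
    k = len(instances)
    return RepertoireBag(sample_id=sample_id, label=label, instances=instances, mask=mask, k=k)
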