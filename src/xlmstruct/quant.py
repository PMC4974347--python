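"""Quantitative comparison of cross-link yields between two protein conformations.

Workflow (mirrors the standard isotope-labelled QCLMS design):

1. Each *sample* mixes the two conditions, one cross-linked with the light
   linker and one with the heavy linker (``label_orientation`` records which
   condition carries the heavy label). Each cross-linked peptide pair
   contributes a log2 signal ratio, always oriented as
   ``log2(condition1 / condition2)`` regardless of label orientation.
2. Within a sample, peptide ratios are normalized to their median (removing
   the condition-mixing bias) and each residue pair takes the median of its
   supporting peptides.
3. Label-swapped replica pairs within an experiment must agree: both
   doublet (averaged) or both singlet for the same condition (a "unique"
   candidate). Pairs quantified in both experiments are averaged.
4. A robust outlier test ("Significance A") on the final fold changes calls
   links significantly enriched in either condition; singlet-validated links
   become unique_1 / unique_2.

Two pairwise comparisons that share a reference condition can be merged
into a six-region Venn classification across three conformations.
"""

from __future__ import annotations

import enum
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from xlmstruct.core import CrossLink, ResidueRef
from xlmstruct.errors import (
    DegenerateSampleError,
    QuantInputError,
    SingletRecordError,
)


class Detection(str, enum.Enum):
    DOUBLET = "doublet"
    SINGLET_CONDITION1 = "singlet_condition1"
    SINGLET_CONDITION2 = "singlet_condition2"


class Category(str, enum.Enum):
    UNIQUE_1 = "unique_1"
    ENRICHED_1 = "enriched_1"
    MUTUAL = "mutual"
    ENRICHED_2 = "enriched_2"
    UNIQUE_2 = "unique_2"


#: Mirror mapping under exchange of the two conditions.
MIRROR = {
    Category.UNIQUE_1: Category.UNIQUE_2,
    Category.ENRICHED_1: Category.ENRICHED_2,
    Category.MUTUAL: Category.MUTUAL,
    Category.ENRICHED_2: Category.ENRICHED_1,
    Category.UNIQUE_2: Category.UNIQUE_1,
}


@dataclass(frozen=True)
class QuantRecord:
    """One peptide pair observed in one quantitation sample."""

    sample_id: str
    experiment_id: str
    label_orientation: str  # condition carrying the HEAVY linker: "condition1"|"condition2"
    peptide_pair_id: str
    crosslink: CrossLink
    area_light: float
    area_heavy: float
    detection: Detection
    replica_pair_id: str = ""

    def __post_init__(self) -> None:
        if self.label_orientation not in ("condition1", "condition2"):
            raise QuantInputError(
                f"label_orientation must be 'condition1' or 'condition2', "
                f"got {self.label_orientation!r}"
            )
        if self.area_light < 0 or self.area_heavy < 0:
            raise QuantInputError("peak areas must be nonnegative")
        det = Detection(self.detection)
        object.__setattr__(self, "detection", det)
        if det is Detection.DOUBLET:
            if not (self.area_light > 0 and self.area_heavy > 0):
                raise QuantInputError("doublet requires both areas > 0")
        else:
            if (self.area_light > 0) == (self.area_heavy > 0):
                raise QuantInputError("singlet requires exactly one area > 0")

    def condition_areas(self) -> tuple[float, float]:
        """(area of condition1, area of condition2) given the label orientation."""
        if self.label_orientation == "condition1":
            return self.area_heavy, self.area_light
        return self.area_light, self.area_heavy


def peptide_log_ratio(rec: QuantRecord) -> float:
    """log2(condition1 / condition2) signal ratio of a doublet peptide pair.

    Orients numerator/denominator by the label orientation so the ratio
    always refers to conditions, not labels. Singlets have no ratio.
    """
    if rec.detection is not Detection.DOUBLET:
        raise SingletRecordError(
            f"record {rec.peptide_pair_id!r} in sample {rec.sample_id!r} is a "
            f"singlet; singlet records feed the unique-category path, not ratios"
        )
    a1, a2 = rec.condition_areas()
    return math.log2(a1 / a2)


def normalize_sample(ratios: Sequence[float]) -> list[float]:
    """Median-center the log ratios of one sample (removes mixing bias)."""
    if len(ratios) == 0:
        raise QuantInputError("cannot normalize an empty ratio list")
    med = float(np.median(ratios))
    return [float(r) - med for r in ratios]


def residue_pair_fold_change(peptide_ratios: Sequence[float]) -> float:
    """Median of the normalized ratios of a residue pair's supporting peptides."""
    if len(peptide_ratios) == 0:
        raise QuantInputError("residue pair has no supporting peptide ratios")
    return float(np.median(peptide_ratios))


# ---------------------------------------------------------------------------
# Replica design and per-sample calls


@dataclass(frozen=True)
class ReplicaDesign:
    """Label-swapped sample pairs, grouped by experiment.

    ``experiments`` maps experiment id to the pair of sample ids whose label
    orientations are swapped.
    """

    experiments: Mapping[str, tuple[str, str]]


def infer_design(records: Iterable[QuantRecord]) -> ReplicaDesign:
    """Derive the replica design from the records themselves.

    Each experiment must contain exactly two samples with opposite label
    orientations.
    """
    seen: dict[str, dict[str, str]] = defaultdict(dict)  # exp -> sample -> orientation
    for rec in records:
        prev = seen[rec.experiment_id].get(rec.sample_id)
        if prev is not None and prev != rec.label_orientation:
            raise QuantInputError(
                f"sample {rec.sample_id!r} has inconsistent label orientations"
            )
        seen[rec.experiment_id][rec.sample_id] = rec.label_orientation
    experiments = {}
    for exp, samples in seen.items():
        if len(samples) != 2:
            raise QuantInputError(
                f"experiment {exp!r} has {len(samples)} samples; expected a "
                f"label-swapped pair"
            )
        (s1, o1), (s2, o2) = sorted(samples.items())
        if o1 == o2:
            raise QuantInputError(
                f"experiment {exp!r} samples {s1!r}/{s2!r} are not label-swapped"
            )
        experiments[exp] = (s1, s2)
    return ReplicaDesign(experiments=experiments)


@dataclass(frozen=True)
class SampleCall:
    """Per-sample summary for one residue pair: a value or a singlet call."""

    kind: str  # "doublet" | "singlet" | "conflict"
    value: Optional[float] = None  # normalized fold change (doublet)
    condition: Optional[int] = None  # 1 or 2 (singlet)
    n_peptides: int = 0


def sample_calls(records: Sequence[QuantRecord]) -> dict[str, dict[CrossLink, SampleCall]]:
    """Summarize every sample: normalized per-residue-pair values and singlet calls.

    Within a sample, normalization uses the median over *all* doublet peptide
    ratios of that sample. A residue pair with any doublet peptide is called
    doublet; otherwise consistent singlets give a singlet call; mixed singlet
    orientations give a conflict.
    """
    by_sample: dict[str, list[QuantRecord]] = defaultdict(list)
    for rec in records:
        by_sample[rec.sample_id].append(rec)

    out: dict[str, dict[CrossLink, SampleCall]] = {}
    for sample_id, recs in by_sample.items():
        doublets = [r for r in recs if r.detection is Detection.DOUBLET]
        raw = [peptide_log_ratio(r) for r in doublets]
        if raw:
            med = float(np.median(raw))
        else:
            med = 0.0
        norm = {id(r): peptide_log_ratio(r) - med for r in doublets}

        per_link: dict[CrossLink, list[QuantRecord]] = defaultdict(list)
        for r in recs:
            per_link[r.crosslink].append(r)

        calls: dict[CrossLink, SampleCall] = {}
        for link, lrecs in per_link.items():
            dbl = [r for r in lrecs if r.detection is Detection.DOUBLET]
            if dbl:
                vals = [norm[id(r)] for r in dbl]
                calls[link] = SampleCall(
                    kind="doublet",
                    value=residue_pair_fold_change(vals),
                    n_peptides=len({r.peptide_pair_id for r in dbl}),
                )
            else:
                conds = {
                    1 if r.detection is Detection.SINGLET_CONDITION1 else 2
                    for r in lrecs
                }
                if len(conds) == 1:
                    calls[link] = SampleCall(
                        kind="singlet",
                        condition=conds.pop(),
                        n_peptides=len({r.peptide_pair_id for r in lrecs}),
                    )
                else:
                    calls[link] = SampleCall(kind="conflict")
        out[sample_id] = calls
    return out


@dataclass
class FoldChange:
    """Accepted, replica-consistent fold change of one residue pair."""

    crosslink: CrossLink
    value: float  # log2(condition1/condition2), median-normalized
    n_supporting_peptides: int
    per_replica_values: list[float] = field(default_factory=list)
    per_experiment_values: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class SingletCall:
    """Replica-consistent singlet: the link was seen in only one condition."""

    crosslink: CrossLink
    condition: int  # 1 or 2
    flags: list[str] = field(default_factory=list)


@dataclass
class Rejected:
    """Residue pair failing the replica-consistency rules."""

    crosslink: CrossLink
    reason: str


def combine_replicas(
    per_sample: Mapping[str, Mapping[CrossLink, SampleCall]],
    design: ReplicaDesign,
):
    """Apply the label-swap replica rules and cross-experiment averaging.

    Within an experiment a residue pair is accepted only if both swapped
    samples quantify it consistently: both doublet (values averaged) or
    both singlet for the same condition. Pairs quantified in both
    experiments take the unweighted mean of the experiment values. A pair
    that is doublet in one experiment but singlet in the other resolves to
    the doublet value with a ``mixed_detection`` flag.

    Returns
    -------
    (fold_changes, singlets, rejected):
        lists of :class:`FoldChange`, :class:`SingletCall`, :class:`Rejected`.
    """
    links: set[CrossLink] = set()
    for calls in per_sample.values():
        links.update(calls)

    fold_changes: list[FoldChange] = []
    singlets: list[SingletCall] = []
    rejected: list[Rejected] = []

    for link in sorted(links, key=lambda ln: ln.positions):
        exp_values: list[float] = []
        exp_singlet_conds: list[int] = []
        replica_values: list[float] = []
        n_pep = 0
        reasons: list[str] = []
        seen_in_some_experiment = False

        for exp, (s1, s2) in sorted(design.experiments.items()):
            c1 = per_sample.get(s1, {}).get(link)
            c2 = per_sample.get(s2, {}).get(link)
            if c1 is None and c2 is None:
                continue
            seen_in_some_experiment = True
            if c1 is None or c2 is None:
                reasons.append(f"{exp}:only_one_replica")
                continue
            if c1.kind == "doublet" and c2.kind == "doublet":
                exp_values.append((c1.value + c2.value) / 2.0)
                replica_values.extend([c1.value, c2.value])
                n_pep += c1.n_peptides + c2.n_peptides
            elif c1.kind == "singlet" and c2.kind == "singlet" and c1.condition == c2.condition:
                exp_singlet_conds.append(c1.condition)
            else:
                reasons.append(f"{exp}:inconsistent_detection")

        if not seen_in_some_experiment:
            continue

        if exp_values:
            flags = []
            if exp_singlet_conds:
                flags.append("mixed_detection")  # doublet in one experiment, singlet in other
            if reasons:
                flags.extend(reasons)
            fold_changes.append(
                FoldChange(
                    crosslink=link,
                    value=float(np.mean(exp_values)),
                    n_supporting_peptides=n_pep,
                    per_replica_values=replica_values,
                    per_experiment_values=exp_values,
                    flags=flags,
                )
            )
        elif exp_singlet_conds:
            if len(set(exp_singlet_conds)) > 1:
                rejected.append(Rejected(link, "conflicting_singlet_conditions"))
            else:
                singlets.append(
                    SingletCall(link, exp_singlet_conds[0], flags=reasons)
                )
        else:
            rejected.append(Rejected(link, ";".join(reasons) or "not_consistently_quantified"))

    return fold_changes, singlets, rejected


# ---------------------------------------------------------------------------
# Significance A and category calls


def significance_A(values: Sequence[float], query: float, min_n: int = 8) -> float:
    """Robust outlier p-value of ``query`` within ``values``.

    The spread on each side of the median is estimated from the 15.87th and
    84.13th percentiles (the one-sigma quantiles of a normal distribution):
    z = (query - m) / (P84.13 - m) on the right, (m - query) / (m - P15.87)
    on the left; p = erfc(z / sqrt(2)) / 2, which lies in (0, 0.5].

    Raises
    ------
    DegenerateSampleError
        For fewer than ``min_n`` values or zero spread on the query's side.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < min_n:
        raise DegenerateSampleError(
            f"need at least {min_n} fold changes for the outlier test, got {vals.size}"
        )
    m = float(np.median(vals))
    if query >= m:
        sigma = float(np.percentile(vals, 84.13)) - m
    else:
        sigma = m - float(np.percentile(vals, 15.87))
    if sigma <= 0:
        raise DegenerateSampleError("zero spread on the query's side of the median")
    z = abs(query - m) / sigma
    return float(0.5 * erfc(z / math.sqrt(2.0)))


@dataclass
class LinkResult:
    crosslink: CrossLink
    category: Category
    fold_change: Optional[float] = None
    p_value: Optional[float] = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    """Five-way classification of one pairwise condition comparison."""

    condition1: str
    condition2: str
    results: dict[CrossLink, LinkResult]
    rejected: list[Rejected] = field(default_factory=list)

    @property
    def n_quantified(self) -> int:
        return len(self.results)

    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in Category}
        for r in self.results.values():
            out[r.category.value] += 1
        return out

    def links_in(self, *categories: Category) -> list[CrossLink]:
        cats = set(categories)
        return [ln for ln, r in self.results.items() if r.category in cats]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ln, r in sorted(self.results.items(), key=lambda kv: kv[0].positions):
            rows.append(
                {
                    "res_a": ln.a.position,
                    "res_b": ln.b.position,
                    "domain_a": ln.a.domain,
                    "domain_b": ln.b.domain,
                    "fold_change": r.fold_change,
                    "p_value": r.p_value,
                    "category": r.category.value,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)


def classify_pairwise(
    fold_changes: Sequence[FoldChange],
    singlets: Sequence[SingletCall],
    alpha: float = 0.05,
    condition1: str = "condition1",
    condition2: str = "condition2",
    rejected: Sequence[Rejected] = (),
) -> ComparisonResult:
    """Assign the five categories from fold changes and singlet calls.

    Significance A runs on the pooled final fold-change values; a link is
    enriched in condition 1 when p < alpha and its fold change lies above
    the sample median (symmetrically for condition 2); otherwise mutual.
    Singlet-validated links become unique_1 / unique_2. If the fold-change
    sample is too small or degenerate for the outlier test, every quantified
    link is mutual.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    results: dict[CrossLink, LinkResult] = {}
    values = [fc.value for fc in fold_changes]
    med = float(np.median(values)) if values else 0.0
    for fc in fold_changes:
        try:
            p = significance_A(values, fc.value)
        except DegenerateSampleError:
            p = None
        if p is not None and p < alpha:
            cat = Category.ENRICHED_1 if fc.value > med else Category.ENRICHED_2
        else:
            cat = Category.MUTUAL
        results[fc.crosslink] = LinkResult(
            fc.crosslink, cat, fold_change=fc.value, p_value=p, flags=list(fc.flags)
        )
    for sg in singlets:
        cat = Category.UNIQUE_1 if sg.condition == 1 else Category.UNIQUE_2
        results[sg.crosslink] = LinkResult(sg.crosslink, cat, flags=list(sg.flags))
    return ComparisonResult(
        condition1=condition1,
        condition2=condition2,
        results=results,
        rejected=list(rejected),
    )


def compare_conditions(
    records: Sequence[QuantRecord],
    condition1: str = "condition1",
    condition2: str = "condition2",
    alpha: float = 0.05,
    design: Optional[ReplicaDesign] = None,
) -> ComparisonResult:
    """Full pipeline: records → per-sample calls → replica rules → categories."""
    if design is None:
        design = infer_design(records)
    per_sample = sample_calls(records)
    fcs, sgs, rej = combine_replicas(per_sample, design)
    return classify_pairwise(
        fcs, sgs, alpha=alpha, condition1=condition1, condition2=condition2, rejected=rej
    )


# ---------------------------------------------------------------------------
# Three-way merge


class VennCategory(str, enum.Enum):
    ALL_THREE = "all_three"
    REFERENCE_ONLY = "reference_only"
    REFERENCE_AND_1 = "reference_and_1"
    REFERENCE_AND_2 = "reference_and_2"
    ONLY_1 = "only_1"
    ONLY_2 = "only_2"
    NOT_REFERENCE = "not_reference"  # theoretically possible, flagged


@dataclass
class ThreeWayResult:
    """Venn classification across the shared reference and two other conditions."""

    reference: str
    condition_a: str
    condition_b: str
    categories: dict[CrossLink, VennCategory]
    conflicts: dict[CrossLink, str] = field(default_factory=dict)

    @property
    def n_quantified(self) -> int:
        return len(self.categories)

    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in VennCategory}
        for c in self.categories.values():
            out[c.value] += 1
        return out


def merge_three_way(cmp_a: ComparisonResult, cmp_b: ComparisonResult) -> ThreeWayResult:
    """Merge two pairwise comparisons sharing their condition-2 reference.

    Both inputs must compare some condition (as condition 1) against the
    same reference (as condition 2). Each link in the union is assigned to
    one of six Venn regions over (reference, A, B); a link its two
    comparisons disagree about — present in the reference per one, absent
    per the other — keeps a conflict flag and is placed by treating the
    reference as present. The seventh region (present in A and B, absent
    from the reference) is allowed but flagged through its own category.
    """
    if cmp_a.condition2 != cmp_b.condition2:
        raise QuantInputError(
            f"comparisons do not share a reference condition: "
            f"{cmp_a.condition2!r} vs {cmp_b.condition2!r}"
        )
    unions = set(cmp_a.results) | set(cmp_b.results)
    categories: dict[CrossLink, VennCategory] = {}
    conflicts: dict[CrossLink, str] = {}

    def presence(res: Optional[LinkResult]):
        """(in_reference, in_other) presence implied by one comparison; None = no info."""
        if res is None:
            return None, False
        if res.category is Category.UNIQUE_1:
            return False, True
        if res.category is Category.UNIQUE_2:
            return True, False
        return True, True

    for link in sorted(unions, key=lambda ln: ln.positions):
        ra = cmp_a.results.get(link)
        rb = cmp_b.results.get(link)
        ref_a, in_a = presence(ra)
        ref_b, in_b = presence(rb)
        refs = {r for r in (ref_a, ref_b) if r is not None}
        if len(refs) == 2:
            conflicts[link] = "conflicting reference-condition singlet calls"
            in_ref = True
        else:
            in_ref = refs.pop()
        if in_ref and in_a and in_b:
            cat = VennCategory.ALL_THREE
        elif in_ref and in_a:
            cat = VennCategory.REFERENCE_AND_1
        elif in_ref and in_b:
            cat = VennCategory.REFERENCE_AND_2
        elif in_ref:
            cat = VennCategory.REFERENCE_ONLY
        elif in_a and in_b:
            cat = VennCategory.NOT_REFERENCE
        elif in_a:
            cat = VennCategory.ONLY_1
        else:
            cat = VennCategory.ONLY_2
        categories[link] = cat

    return ThreeWayResult(
        reference=cmp_a.condition2,
        condition_a=cmp_a.condition1,
        condition_b=cmp_b.condition1,
        categories=categories,
        conflicts=conflicts,
    )


# ---------------------------------------------------------------------------
# Table I/O

REQUIRED_COLUMNS = [
    "sample_id",
    "experiment_id",
    "label_orientation",
    "peptide_pair_id",
    "res_a",
    "res_b",
    "area_light",
    "area_heavy",
    "detection",
]


def read_quant_table(path) -> list[QuantRecord]:
    """Read a TSV quantitation table (one row per peptide pair per sample).

    Malformed rows are rejected with their 1-based line number in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "experiment_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise QuantInputError(f"quantitation table missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            link = CrossLink(
                ResidueRef(int(row.res_a), residue_type=getattr(row, "type_a", "unknown")),
                ResidueRef(int(row.res_b), residue_type=getattr(row, "type_b", "unknown")),
            )
            records.append(
                QuantRecord(
                    sample_id=str(row.sample_id),
                    experiment_id=str(row.experiment_id),
                    label_orientation=str(row.label_orientation),
                    peptide_pair_id=str(row.peptide_pair_id),
                    crosslink=link,
                    area_light=float(row.area_light),
                    area_heavy=float(row.area_heavy),
                    detection=Detection(str(row.detection)),
                    replica_pair_id=str(getattr(row, "replica_pair_id", "")),
                )
            )
        except (ValueError, QuantInputError) as exc:
            raise QuantInputError(f"line {line}: {exc}") from exc
    return records


def records_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "experiment_id": r.experiment_id,
                "label_orientation": r.label_orientation,
                "peptide_pair_id": r.peptide_pair_id,
                "res_a": r.crosslink.a.position,
                "res_b": r.crosslink.b.position,
                "area_light": r.area_light,
                "area_heavy": r.area_heavy,
                "detection": r.detection.value,
            }
        )
    return pd.DataFrame(rows)
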