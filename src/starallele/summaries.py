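"""Cohort-level frequency tables, per-gene summaries, and novelty reports.

Haplotype (star-allele) frequencies are computed over the 2N haplotype slots
of an N-sample cohort; diplotype frequencies over the N samples. Ambiguous
calls are counted under their own ``*Amb`` label by default and can be
excluded, in which case frequencies renormalise over the retained slots.

The per-gene summary counts the distinct non-ambiguous alleles and diplotypes
observed and expresses the allele count as a proportion of the alleles in the
loaded definition set (reference included — the definition-table row universe
is the denominator convention here). Novelty against an external reference
call set conservatively excludes ambiguous calls and any allele token carrying
a copy-number suffix (``*2x2``) or a tandem arrangement (``*36+*10``), since
those reflect structural variation rather than a new sequence-defined allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .concordance import parse_diplotype
from .definitions import DefinitionSet
from .matcher import DiplotypeCall

__all__ = [
    "FrequencyTable",
    "GeneSummary",
    "NoveltyReport",
    "allele_frequencies",
    "diplotype_frequencies",
    "gene_summary",
    "proportion_observed",
    "novelty",
]

HAPLOTYPE = "HAPLOTYPE"
DIPLOTYPE = "DIPLOTYPE"


@dataclass(frozen=True)
class FrequencyTable:
    gene: str
    unit: str  # HAPLOTYPE or DIPLOTYPE
    entries: Mapping[str, tuple[int, float]]  # label -> (count, frequency)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": self.gene, "label": label, "count": c, "frequency": f}
            for label, (c, f) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "label", "count", "frequency"])


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    n_unique_diplotypes: int
    n_unique_alleles: int
    n_pharmvar_alleles: int
    proportion_observed: float


@dataclass(frozen=True)
class NoveltyReport:
    gene: str
    new_alleles: frozenset[str]
    new_diplotypes: frozenset[str]


def _gene_calls(calls: Iterable[DiplotypeCall], gene: str) -> list[DiplotypeCall]:
    return [c for c in calls if c.gene == gene]


def _tabulate(counts: dict[str, int], gene: str, unit: str) -> FrequencyTable:
    total = sum(counts.values())
    entries = {
        label: (n, n / total if total else 0.0) for label, n in counts.items()
    }
    return FrequencyTable(gene=gene, unit=unit, entries=entries)


def allele_frequencies(
    calls: Iterable[DiplotypeCall], gene: str, exclude_amb: bool = False
) -> FrequencyTable:
    """Star-allele (haplotype) counts and frequencies over 2N slots."""
    counts: dict[str, int] = {}
    for c in _gene_calls(calls, gene):
        for hap in (c.hap1, c.hap2):
            if exclude_amb and hap.is_amb:
                continue
            counts[hap.label] = counts.get(hap.label, 0) + 1
    return _tabulate(counts, gene, HAPLOTYPE)


def diplotype_frequencies(
    calls: Iterable[DiplotypeCall],
    gene: str,
    normalize_unordered: bool = False,
    exclude_amb: bool = False,
) -> FrequencyTable:
    """Diplotype counts and frequencies over N samples.

    With ``normalize_unordered`` the phased label is collapsed to unordered
    slash notation with alleles in ascending order, so ``*2|*1`` and
    ``*1|*2`` pool into a single ``*1/*2`` entry.
    """
    counts: dict[str, int] = {}
    for c in _gene_calls(calls, gene):
        if exclude_amb and c.has_amb:
            continue
        label = (
            parse_diplotype(c.phased_label).normalized_label()
            if normalize_unordered
            else c.phased_label
        )
        counts[label] = counts.get(label, 0) + 1
    return _tabulate(counts, gene, DIPLOTYPE)


def proportion_observed(n_unique_alleles: int, n_pharmvar_alleles: int) -> float:
    """Observed fraction of catalogued alleles, rounded half-up to 2 decimals."""
    if n_pharmvar_alleles == 0:
        raise ValueError("n_pharmvar_alleles must be positive")
    frac = Decimal(n_unique_alleles) / Decimal(n_pharmvar_alleles)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _simple_allele_labels(call: DiplotypeCall) -> list[str] | None:
    """Both allele labels if the diplotype is non-Amb and free of copy-number
    or tandem tokens; None otherwise."""
    if call.has_amb:
        return None
    dip = parse_diplotype(call.phased_label)
    if any(t.has_copy_gain or t.is_composite for t in dip.alleles):
        return None
    return [str(t) for t in dip.alleles]


def gene_summary(
    calls: Iterable[DiplotypeCall],
    defs: DefinitionSet | None = None,
    n_pharmvar_alleles: int | None = None,
) -> GeneSummary:
    """Distinct non-ambiguous diplotypes/alleles and catalogue coverage.

    The catalogue size comes from ``defs`` (all alleles in the loaded
    definition set, reference included) unless ``n_pharmvar_alleles``
    overrides it. Diplotypes are counted as unordered allele pairs; ambiguous
    and structural-variant calls are excluded from both unique counts.
    """
    if defs is None and n_pharmvar_alleles is None:
        raise ValueError("either defs or n_pharmvar_alleles is required")
    gene = defs.gene if defs is not None else next(iter(calls)).gene
    call_list = _gene_calls(calls, gene)
    n_cat = n_pharmvar_alleles if n_pharmvar_alleles is not None else defs.n_alleles()
    alleles: set[str] = set()
    diplotypes: set[str] = set()
    for c in call_list:
        labels = _simple_allele_labels(c)
        if labels is None:
            continue
        alleles.update(labels)
        diplotypes.add(parse_diplotype(c.phased_label).normalized_label())
    return GeneSummary(
        gene=gene,
        n_unique_diplotypes=len(diplotypes),
        n_unique_alleles=len(alleles),
        n_pharmvar_alleles=n_cat,
        proportion_observed=proportion_observed(len(alleles), n_cat),
    )


def novelty(
    calls: Iterable[DiplotypeCall],
    gene: str,
    reference_alleles: Iterable[str],
    reference_diplotypes: Iterable[str],
) -> NoveltyReport:
    """Alleles and diplotypes observed in the cohort but absent elsewhere.

    Ambiguous calls and diplotypes with copy-number (``x<n>``) or tandem
    (``+``) tokens are excluded before the set difference, on both sides.
    Reference diplotypes are normalised to unordered ascending notation.
    """
    obs_alleles: set[str] = set()
    obs_diplotypes: set[str] = set()
    for c in _gene_calls(calls, gene):
        labels = _simple_allele_labels(c)
        if labels is None:
            continue
        obs_alleles.update(labels)
        obs_diplotypes.add(parse_diplotype(c.phased_label).normalized_label())
    ref_alleles = set(reference_alleles)
    ref_diplotypes = set()
    for d in reference_diplotypes:
        dip = parse_diplotype(d)
        if dip.has_amb or any(t.has_copy_gain or t.is_composite for t in dip.alleles):
            continue
        ref_diplotypes.add(dip.normalized_label())
    return NoveltyReport(
        gene=gene,
        new_alleles=frozenset(obs_alleles - ref_alleles),
        new_diplotypes=frozenset(obs_diplotypes - ref_diplotypes),
    )
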