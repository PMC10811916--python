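"""Strict star-allele assignment for phased haplotypes.

A haplotype is annotated with a star allele only when its set of non-reference
variants at the gene's definition positions equals exactly one allele's
defining set (a *complete match*). Anything else — extra variants beyond a
defining set, a partial match, two alleles with identical defining sets,
a missing genotype, or an unphased heterozygote — is ambiguous (``*Amb``).
The reference call (``*1``) is an absence claim: it requires an empty
non-reference set *and* no missing or unphased flags.

Diplotypes preserve the phased GT order: a sample whose first haplotype
matches *61 and whose second is reference renders ``*61|*1``, never
``*1|*61``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .definitions import DefinitionSet, VariantKey
from .vcfio import HaplotypeObservation, scan_region

__all__ = [
    "AMB",
    "AMB_LABEL",
    "HaplotypeCall",
    "DiplotypeCall",
    "match_haplotype",
    "call_sample",
    "call_cohort",
    "calls_to_frame",
    "CALL_COLUMNS",
]

AMB = "AMB"
AMB_LABEL = "*Amb"

# machine-readable reason codes
EXACT_MATCH = "EXACT_MATCH"
REFERENCE = "REFERENCE"
NO_MATCH = "NO_MATCH"
SUPERSET = "SUPERSET"
MULTI_MATCH = "MULTI_MATCH"
MISSING_GT = "MISSING_GT"
UNPHASED = "UNPHASED"

ENGINE = "ENGINE"
EXTERNAL_CYP2D6 = "EXTERNAL_CYP2D6"


@dataclass(frozen=True)
class HaplotypeCall:
    sample: str
    hap_index: int
    call: str  # allele name, reference name, or AMB
    reason: str
    matched_variants: frozenset[VariantKey] = frozenset()
    extra_variants: frozenset[VariantKey] = frozenset()

    @property
    def label(self) -> str:
        return AMB_LABEL if self.call == AMB else self.call

    @property
    def is_amb(self) -> bool:
        return self.call == AMB


@dataclass(frozen=True)
class DiplotypeCall:
    sample: str
    gene: str
    hap1: HaplotypeCall
    hap2: HaplotypeCall
    source: str = ENGINE

    @property
    def phased_label(self) -> str:
        return f"{self.hap1.label}|{self.hap2.label}"

    @property
    def has_amb(self) -> bool:
        return self.hap1.is_amb or self.hap2.is_amb


def match_haplotype(obs: HaplotypeObservation, defs: DefinitionSet) -> HaplotypeCall:
    """Assign a star allele to one haplotype by strict set matching.

    Decision order: missing genotype or unphased het → ``Amb``; empty
    non-reference set → reference; exactly one allele whose defining set
    equals the observed set → that allele; several equal → ``Amb``
    (MULTI_MATCH); a defining set strictly contained in the observation →
    ``Amb`` (SUPERSET, with the unexplained variants reported); otherwise
    ``Amb`` (NO_MATCH). Total on valid inputs.
    """
    if obs.missing_sites:
        return HaplotypeCall(obs.sample, obs.hap_index, AMB, MISSING_GT)
    if obs.unphased_het:
        return HaplotypeCall(obs.sample, obs.hap_index, AMB, UNPHASED)
    present = frozenset(obs.present)
    if not present:
        return HaplotypeCall(obs.sample, obs.hap_index, defs.reference_name, REFERENCE)
    exact = [a for a in defs.defined_alleles if a.defining == present]
    if len(exact) == 1:
        return HaplotypeCall(
            obs.sample, obs.hap_index, exact[0].name, EXACT_MATCH,
            matched_variants=present,
        )
    if len(exact) > 1:
        return HaplotypeCall(
            obs.sample, obs.hap_index, AMB, MULTI_MATCH, matched_variants=present
        )
    contained = [a for a in defs.defined_alleles if a.defining < present]
    if contained:
        largest = max(contained, key=lambda a: len(a.defining))
        return HaplotypeCall(
            obs.sample, obs.hap_index, AMB, SUPERSET,
            matched_variants=frozenset(largest.defining),
            extra_variants=present - largest.defining,
        )
    return HaplotypeCall(obs.sample, obs.hap_index, AMB, NO_MATCH,
                         extra_variants=present)


def call_sample(
    hap1_obs: HaplotypeObservation,
    hap2_obs: HaplotypeObservation,
    defs: DefinitionSet,
) -> DiplotypeCall:
    """Assemble a phased diplotype from one sample's two haplotypes.

    GT order is preserved; no normalisation or sorting of the pair.
    """
    if hap1_obs.sample != hap2_obs.sample:
        raise ValueError(
            f"haplotypes from different samples: {hap1_obs.sample} vs {hap2_obs.sample}"
        )
    return DiplotypeCall(
        sample=hap1_obs.sample,
        gene=defs.gene,
        hap1=match_haplotype(hap1_obs, defs),
        hap2=match_haplotype(hap2_obs, defs),
    )


def call_cohort(
    vcf: str,
    defsets: Mapping[str, DefinitionSet] | Iterable[DefinitionSet],
    samples: list[str] | None = None,
) -> list[DiplotypeCall]:
    """Call every (sample, gene) diplotype in a phased cohort VCF.

    Rows are ordered by gene then sample; a definition position absent from
    the file is treated as homozygous reference for all samples (visible in
    the per-gene SiteCoverage from :func:`scan_region` for callers that want
    to warn).
    """
    if isinstance(defsets, Mapping):
        genes = [defsets[g] for g in sorted(defsets)]
    else:
        genes = sorted(defsets, key=lambda d: d.gene)
    calls: list[DiplotypeCall] = []
    for defs in genes:
        obs, _cov = scan_region(vcf, defs, samples=samples)
        for sample in sorted(obs):
            o1, o2 = obs[sample]
            calls.append(call_sample(o1, o2, defs))
    return calls


CALL_COLUMNS = ["sample", "gene", "hap1", "hap2", "diplotype", "reason1", "reason2", "source"]


def calls_to_frame(calls: Iterable[DiplotypeCall]) -> pd.DataFrame:
    """Tabulate diplotype calls with the fixed output column order."""
    rows = [
        {
            "sample": c.sample,
            "gene": c.gene,
            "hap1": c.hap1.label,
            "hap2": c.hap2.label,
            "diplotype": c.phased_label,
            "reason1": c.hap1.reason,
            "reason2": c.hap2.reason,
            "source": c.source,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def calls_from_frame(df: pd.DataFrame) -> list[DiplotypeCall]:
    """Rebuild diplotype calls from the tabular CSV form."""
    out = []
    for row in df.itertuples(index=False):
        h1 = HaplotypeCall(row.sample, 1,
                           AMB if row.hap1 == AMB_LABEL else row.hap1,
                           getattr(row, "reason1", ""))
        h2 = HaplotypeCall(row.sample, 2,
                           AMB if row.hap2 == AMB_LABEL else row.hap2,
                           getattr(row, "reason2", ""))
        out.append(DiplotypeCall(sample=row.sample, gene=row.gene,
                                 hap1=h1, hap2=h2,
                                 source=getattr(row, "source", ENGINE)))
    return out
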