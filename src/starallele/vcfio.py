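"""Projection of phased VCF genotypes onto a gene's definition positions.

Each diploid sample is split into two haplotype observations (haplotype 1 is
the left side of the ``|``-separated GT). Only records whose
``(chrom, pos, ref, alt)`` — after multiallelic decomposition and ``chr``
prefix normalisation — matches a defining variant of the gene contribute.
Definition positions with no record in the file at all are reported in
:class:`SiteCoverage`; downstream they behave as homozygous reference, which
is exactly how a phased short-read call set that simply lacks a deletion
record behaves.

Missing genotypes (``.``) at a definition position are recorded per
haplotype in ``missing_sites``; an unphased heterozygote (``0/1``) flags both
haplotypes as phase-ambiguous. Homozygous unphased genotypes (``1/1``) carry
no phase ambiguity and are accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cyvcf2 import VCF

from .definitions import DefinitionSet, VariantKey, definition_positions, normalize_chrom

__all__ = ["HaplotypeObservation", "SiteCoverage", "scan_region", "decompose_multiallelic"]

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeObservation:
    """One sample-haplotype's non-reference content over definition positions."""

    sample: str
    hap_index: int  # 1 or 2, VCF GT order
    present: set[VariantKey] = field(default_factory=set)
    missing_sites: set[VariantKey] = field(default_factory=set)
    unphased_het: bool = False

    def __post_init__(self) -> None:
        if self.hap_index not in (1, 2):
            raise ValueError(f"hap_index must be 1 or 2, got {self.hap_index}")


@dataclass(frozen=True)
class SiteCoverage:
    """Which of a gene's definition positions the VCF actually contains."""

    requested: frozenset[VariantKey]
    found_in_file: frozenset[VariantKey]

    @property
    def absent_from_file(self) -> frozenset[VariantKey]:
        return self.requested - self.found_in_file


class VcfFormatError(ValueError):
    """Raised for VCFs that violate the diploid phased-GT contract."""


def _diploid_gt(variant, sample: str, gt) -> tuple[int, int, bool]:
    """Return (hap1 allele index, hap2 allele index, phased); -1 = missing."""
    if len(gt) == 3:
        return int(gt[0]), int(gt[1]), bool(gt[2])
    raise VcfFormatError(
        f"non-diploid genotype for sample {sample} at "
        f"{variant.CHROM}:{variant.POS}"
    )


def decompose_multiallelic(variant) -> list[tuple[VariantKey, list[tuple[bool, bool]]]]:
    """Split one (possibly multiallelic) record into biallelic keys.

    Returns one ``(VariantKey, presence)`` entry per non-symbolic ALT, where
    ``presence[i]`` is a ``(hap1, hap2)`` boolean pair for the i-th sample: a
    haplotype is present for ALT *k* iff its genotype index equals *k*.
    Symbolic ALTs (``<DEL>`` etc.) are skipped with a warning.
    """
    chrom = normalize_chrom(variant.CHROM)
    out: list[tuple[VariantKey, list[tuple[bool, bool]]]] = []
    gts = variant.genotypes
    for k, alt in enumerate(variant.ALT, start=1):
        if alt.startswith("<") or alt == "*":
            logger.warning(
                "skipping symbolic ALT %s at %s:%d", alt, variant.CHROM, variant.POS
            )
            continue
        key = VariantKey(chrom, variant.POS, variant.REF, alt, variant.ID or "")
        presence = []
        for i, gt in enumerate(gts):
            a, b, _ = _diploid_gt(variant, f"sample#{i}", gt)
            presence.append((a == k, b == k))
        out.append((key, presence))
    return out


def scan_region(
    vcf: str,
    defs: DefinitionSet,
    samples: list[str] | None = None,
) -> tuple[dict[str, tuple[HaplotypeObservation, HaplotypeObservation]], SiteCoverage]:
    """Project every sample of a phased VCF onto one gene's definition positions.

    Parameters
    ----------
    vcf
        Path to a VCF (plain or bgzipped) with a GT FORMAT field and diploid
        samples. Multiallelic records are decomposed.
    defs
        The gene's definition set; only its definition positions are scanned.
    samples
        Optional subset of sample names to project.

    Returns
    -------
    observations, coverage
        ``observations[sample] = (hap1_obs, hap2_obs)`` and a
        :class:`SiteCoverage` reporting definition positions with no record
        in the file.
    """
    requested = frozenset(definition_positions(defs))
    wanted: dict[tuple[str, int, str, str], VariantKey] = {
        (v.chrom, v.pos, v.ref, v.alt): v for v in requested
    }
    reader = VCF(vcf, samples=samples, gts012=False)
    try:
        if samples is not None:
            missing = set(samples) - set(reader.samples)
            if missing:
                raise VcfFormatError(f"samples not in VCF: {sorted(missing)}")
        names = list(reader.samples)
        obs = {
            s: (HaplotypeObservation(s, 1), HaplotypeObservation(s, 2)) for s in names
        }
        found: set[VariantKey] = set()
        for variant in reader:
            if variant.CHROM is None:
                continue
            chrom = normalize_chrom(variant.CHROM)
            # cheap positional pre-filter before decomposition
            if not any((chrom, variant.POS, variant.REF, alt) in wanted
                       for alt in variant.ALT):
                continue
            if names and "GT" not in (variant.FORMAT or []):
                raise VcfFormatError(
                    f"record {variant.CHROM}:{variant.POS} has no GT field"
                )
            gts = variant.genotypes if names else []
            matched: list[tuple[int, VariantKey]] = []
            for k, alt in enumerate(variant.ALT, start=1):
                key = wanted.get((chrom, variant.POS, variant.REF, alt))
                if key is not None:
                    matched.append((k, key))
                    found.add(key)
            if not matched:
                continue
            for i, name in enumerate(names):
                a, b, phased = _diploid_gt(variant, name, gts[i])
                o1, o2 = obs[name]
                if a >= 0 and b >= 0 and a != b and not phased:
                    o1.unphased_het = True
                    o2.unphased_het = True
                for hap_allele, o in ((a, o1), (b, o2)):
                    if hap_allele == -1:
                        o.missing_sites.update(key for _, key in matched)
                    else:
                        for k, key in matched:
                            if hap_allele == k:
                                o.present.add(key)
        return obs, SiteCoverage(requested=requested, found_in_file=frozenset(found))
    finally:
        reader.close()
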