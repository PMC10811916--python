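"""Phased-cohort simulation with known truth, and cohort variant-QC filters.

The simulator emulates the input a large phased WGS call set provides: a
multi-sample VCF restricted to a gene's allele-defining positions, with
diploid ``|``-phased genotypes, an optional trio pedigree, and a truth table
of each sample's simulated diplotype. Unrelated haplotypes are drawn i.i.d.
from user-specified star-allele frequencies; trio children inherit one
haplotype from each parent without recombination (pharmacogene loci are
short). Documented failure modes of real call sets can be injected: whole
definition sites absent from the file (``drop_sites``, e.g. an uncalled
single-base deletion), missing genotypes, and unphased heterozygotes.

The QC filters reproduce standard pre-phasing cohort hygiene: a site is kept
when its missing-genotype rate is below 5%, its Hardy-Weinberg exact test
P-value exceeds 1e-10, its Mendelian error rate over complete trios is at
most 5%, and its minor allele count is at least 2. The Hardy-Weinberg test is
the exact conditional test: conditioning on the allele counts, it sums the
probabilities of all heterozygote counts no more likely than the observed one
(two-sided "no more likely" mass summation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

from .definitions import DefinitionSet, VariantKey, definition_positions

__all__ = [
    "SimConfig",
    "SimTruth",
    "QCThresholds",
    "simulate_cohort",
    "genotype_array",
    "missing_rate",
    "hwe_exact_p",
    "mendel_error_rate",
    "minor_allele_count",
    "apply_filters",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-site retention thresholds for cohort variant QC."""

    max_missing_rate: float = 0.05
    min_hwe_p: float = 1e-10
    max_mendel_rate: float = 0.05
    min_mac: int = 2


@dataclass
class SimConfig:
    """Configuration for one simulated phased cohort.

    ``hap_freqs`` maps each gene to ``{allele name: frequency}`` summing to 1;
    ``n_samples`` counts all individuals, of which ``3 * n_trios`` form
    father/mother/child trios and the rest are unrelated. Artifact knobs:
    ``drop_sites`` removes whole records from the emitted VCF (truth is
    unchanged), ``missing_rate``/``unphase_rate`` are per-(site, sample)
    probabilities of a missing genotype / an unphased heterozygote.
    """

    defs: Mapping[str, DefinitionSet]
    hap_freqs: Mapping[str, Mapping[str, float]]
    n_samples: int
    n_trios: int = 0
    seed: int = 0
    drop_sites: frozenset[VariantKey] = frozenset()
    missing_rate: float = 0.0
    unphase_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_trios < 0 or 3 * self.n_trios > self.n_samples:
            raise ValueError("need 0 <= 3 * n_trios <= n_samples")
        for gene, freqs in self.hap_freqs.items():
            if gene not in self.defs:
                raise ValueError(f"hap_freqs gene {gene} has no definition set")
            ds = self.defs[gene]
            total = 0.0
            for allele, f in freqs.items():
                if allele not in ds.alleles:
                    raise ValueError(f"allele {allele} not defined for {gene}")
                if f < 0:
                    raise ValueError(f"negative frequency for {gene} {allele}")
                total += f
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene} haplotype frequencies sum to {total}, not 1")
        for gene in self.defs:
            if gene not in self.hap_freqs:
                raise ValueError(f"no haplotype frequencies for gene {gene}")


@dataclass(frozen=True)
class SimTruth:
    """True ordered diplotypes keyed by (sample, gene)."""

    diplotypes: Mapping[tuple[str, str], tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "gene": g, "hap1": a, "hap2": b}
            for (s, g), (a, b) in sorted(self.diplotypes.items())
        ]
        return pd.DataFrame(rows, columns=["sample", "gene", "hap1", "hap2"])


@dataclass(frozen=True)
class SimResult:
    vcf_text: str
    truth: SimTruth
    pedigree: pd.DataFrame  # columns family, child, father, mother
    samples: list[str] = field(default_factory=list)

    def write(self, vcf_path: str, truth_path: str | None = None,
              ped_path: str | None = None) -> None:
        with open(vcf_path, "wt", encoding="utf-8") as fh:
            fh.write(self.vcf_text)
        if truth_path:
            self.truth.to_frame().to_csv(truth_path, index=False)
        if ped_path:
            self.pedigree.to_csv(ped_path, sep="\t", index=False)


def _sample_names(n_samples: int, n_trios: int) -> tuple[list[str], pd.DataFrame]:
    names: list[str] = []
    ped_rows = []
    for t in range(1, n_trios + 1):
        fam = f"T{t:03d}"
        fa, mo, ch = f"{fam}_F", f"{fam}_M", f"{fam}_C"
        names += [fa, mo, ch]
        ped_rows.append({"family": fam, "child": ch, "father": fa, "mother": mo})
    for i in range(1, n_samples - 3 * n_trios + 1):
        names.append(f"S{i:04d}")
    ped = pd.DataFrame(ped_rows, columns=["family", "child", "father", "mother"])
    return names, ped


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate a phased cohort VCF, its truth table, and its pedigree.

    Deterministic for a given config (byte-identical VCF text per seed).
    Records are biallelic (one per defining variant), sorted by position, GT
    phased with ``|`` unless an artifact switches a heterozygote to ``/`` or
    blanks the genotype.
    """
    rng = np.random.default_rng(cfg.seed)
    names, ped = _sample_names(cfg.n_samples, cfg.n_trios)
    genes = sorted(cfg.defs)
    truth: dict[tuple[str, str], tuple[str, str]] = {}
    # per gene: sample -> (allele1, allele2)
    hap_alleles: dict[str, dict[str, tuple[str, str]]] = {}
    for gene in genes:
        freqs = cfg.hap_freqs[gene]
        alleles = sorted(freqs)
        probs = np.array([freqs[a] for a in alleles], dtype=float)
        probs = probs / probs.sum()
        assign: dict[str, tuple[str, str]] = {}
        for t in range(1, cfg.n_trios + 1):
            fam = f"T{t:03d}"
            fa = tuple(rng.choice(alleles, size=2, p=probs))
            mo = tuple(rng.choice(alleles, size=2, p=probs))
            ch = (fa[int(rng.integers(2))], mo[int(rng.integers(2))])
            assign[f"{fam}_F"], assign[f"{fam}_M"], assign[f"{fam}_C"] = fa, mo, ch
        for i in range(1, cfg.n_samples - 3 * cfg.n_trios + 1):
            assign[f"S{i:04d}"] = tuple(rng.choice(alleles, size=2, p=probs))
        hap_alleles[gene] = assign
        for s in names:
            truth[(s, gene)] = assign[s]

    out = io.StringIO()
    out.write("##fileformat=VCFv4.3\n")
    out.write(f"##source=starallele simulate seed={cfg.seed}\n")
    contigs = sorted(
        {v.chrom for g in genes for v in definition_positions(cfg.defs[g])}
    )
    for c in contigs:
        out.write(f"##contig=<ID={c}>\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(names) + "\n")

    records: list[tuple[VariantKey, str]] = []
    for gene in genes:
        ds = cfg.defs[gene]
        assign = hap_alleles[gene]
        defining = {name: ds.alleles[name].defining for name in ds.alleles}
        for key in definition_positions(ds):
            if key in cfg.drop_sites:
                continue
            gts = []
            for s in names:
                a1, a2 = assign[s]
                g1 = int(key in defining[a1])
                g2 = int(key in defining[a2])
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    gts.append(".|.")
                    continue
                sep = "|"
                if (g1 != g2 and cfg.unphase_rate > 0
                        and rng.random() < cfg.unphase_rate):
                    sep = "/"
                gts.append(f"{g1}{sep}{g2}")
            line = "\t".join(
                [key.chrom, str(key.pos), key.rsid or ".", key.ref, key.alt,
                 ".", "PASS", ".", "GT"] + gts
            )
            records.append((key, line))
    for _, line in sorted(records, key=lambda kv: kv[0]):
        out.write(line + "\n")
    return SimResult(vcf_text=out.getvalue(), truth=SimTruth(truth),
                     pedigree=ped, samples=names)


# --- per-record QC metrics -------------------------------------------------

def genotype_array(variant) -> np.ndarray:
    """(n_samples, 2) allele-index array from a cyvcf2 record; -1 = missing."""
    gts = variant.genotypes
    return np.array([[g[0], g[1]] for g in gts], dtype=int)


def missing_rate(gts: np.ndarray) -> float:
    """Fraction of samples whose genotype is (even partially) uncalled."""
    if len(gts) == 0:
        raise ValueError("no samples")
    return float(np.mean((gts < 0).any(axis=1)))


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test P-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    the observed one. Monomorphic sites have a single outcome and P = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa  # minor-or-not is irrelevant: the test is symmetric
    n_A = 2 * n_AA + n_Aa

    def log_prob(h: int) -> float:
        haa = (n_a - h) // 2
        hAA = n - h - haa
        return (
            h * np.log(2.0)
            + gammaln(n + 1) - gammaln(hAA + 1) - gammaln(h + 1) - gammaln(haa + 1)
            + gammaln(n_a + 1) + gammaln(n_A + 1) - gammaln(2 * n + 1)
        )

    h_values = [h for h in range(n_a % 2, min(n_a, n_A) + 1, 2)]
    logs = np.array([log_prob(h) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[h_values.index(n_Aa)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def minor_allele_count(gts: np.ndarray) -> int:
    """Minor allele count over called haplotypes at a biallelic site."""
    called = gts[gts >= 0]
    n_alt = int((called > 0).sum())
    n_ref = int((called == 0).sum())
    return min(n_ref, n_alt)


_ALLOWED = {-1: frozenset(), 0: frozenset({0}), 1: frozenset({0, 1}),
            2: frozenset({1})}


def _transmissible(parent_gt: np.ndarray) -> frozenset[int]:
    return frozenset(int(a) for a in parent_gt)


def mendel_error_rate(
    gts: np.ndarray, samples: list[str], pedigree: pd.DataFrame
) -> float:
    """Fraction of fully-genotyped trios with an impossible child genotype.

    A child genotype (as an unordered allele pair) is possible iff one allele
    can come from the father's pair and the other from the mother's. Trios
    with any uncalled member are excluded from the denominator; with no
    evaluable trio the rate is 0.
    """
    idx = {s: i for i, s in enumerate(samples)}
    n_eval = 0
    n_err = 0
    for row in pedigree.itertuples(index=False):
        try:
            gc = gts[idx[row.child]]
            gf = gts[idx[row.father]]
            gm = gts[idx[row.mother]]
        except KeyError as exc:
            raise ValueError(f"pedigree member absent from cohort: {exc}") from exc
        if (gc < 0).any() or (gf < 0).any() or (gm < 0).any():
            continue
        n_eval += 1
        fa, mo = _transmissible(gf), _transmissible(gm)
        c1, c2 = int(gc[0]), int(gc[1])
        ok = (c1 in fa and c2 in mo) or (c2 in fa and c1 in mo)
        if not ok:
            n_err += 1
    return n_err / n_eval if n_eval else 0.0


def _record_metrics(variant, samples, pedigree, thresholds):
    gts = genotype_array(variant)
    miss = missing_rate(gts)
    called = gts[(gts >= 0).all(axis=1)]
    n_aa = int(((called > 0).sum(axis=1) == 2).sum())
    n_het = int(((called > 0).sum(axis=1) == 1).sum())
    n_AA = len(called) - n_aa - n_het
    hwe = hwe_exact_p(n_AA, n_het, n_aa) if len(called) else 0.0
    mendel = (
        mendel_error_rate(gts, samples, pedigree)
        if pedigree is not None and len(pedigree)
        else 0.0
    )
    mac = minor_allele_count(gts)
    failures = []
    if not miss < thresholds.max_missing_rate:
        failures.append("missing_rate")
    if not hwe > thresholds.min_hwe_p:
        failures.append("hwe")
    if not mendel <= thresholds.max_mendel_rate:
        failures.append("mendel")
    if not mac >= thresholds.min_mac:
        failures.append("mac")
    return miss, hwe, mendel, mac, failures


def apply_filters(
    vcf: str,
    pedigree: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
    out_vcf: str | None = None,
) -> pd.DataFrame:
    """Apply per-site cohort QC and optionally write the filtered VCF.

    A record is retained iff missing rate < ``max_missing_rate``, exact HWE
    P-value > ``min_hwe_p``, Mendelian error rate ≤ ``max_mendel_rate`` and
    minor allele count ≥ ``min_mac``. Returns the per-record decision table;
    filtering is idempotent. Multiallelic records are evaluated with all
    alternate alleles pooled.
    """
    reader = VCF(vcf, gts012=False)
    try:
        samples = list(reader.samples)
        rows = []
        kept_lines = []
        for variant in reader:
            miss, hwe, mendel, mac, failures = _record_metrics(
                variant, samples, pedigree, thresholds
            )
            retained = not failures
            rows.append(
                {
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "ref": variant.REF,
                    "alt": ",".join(variant.ALT),
                    "missing_rate": miss,
                    "hwe_p": hwe,
                    "mendel_rate": mendel,
                    "mac": mac,
                    "retained": retained,
                    "failed": ";".join(failures),
                }
            )
            if retained:
                kept_lines.append(str(variant).rstrip("\n"))
        if out_vcf is not None:
            with open(out_vcf, "wt", encoding="utf-8") as fh:
                fh.write(reader.raw_header)
                for line in kept_lines:
                    fh.write(line + "\n")
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "missing_rate", "hwe_p",
                     "mendel_rate", "mac", "retained", "failed"],
        )
    finally:
        reader.close()
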