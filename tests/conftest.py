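"""Shared fixtures: small CYP2C19/CYP2C9 definition sets and a VCF writer.

Coordinates and defining-variant memberships follow the published PharmVar
core-allele content for the alleles exercised here (CYP2C19 *2/*35, CYP2C9
*2/*61/*6). The CYP2C19 *15 entry is a synthetic stand-in: only the relevance
of rs17882687 to *15 matters for these tests, not the full catalogue
definition.
"""

from __future__ import annotations

import io

import pytest

from starallele.definitions import DefinitionSet, VariantKey, parse_definition_table

CYP2C19_TSV = """gene\tallele\tchrom\tpos\tref\talt\trsid
CYP2C19\t*2\t10\t94762706\tG\tA\trs12769205
CYP2C19\t*2\t10\t94781859\tG\tA\trs4244285
CYP2C19\t*2\t10\t94842866\tA\tG\trs3758581
CYP2C19\t*35\t10\t94762706\tG\tA\trs12769205
CYP2C19\t*35\t10\t94842866\tA\tG\trs3758581
CYP2C19\t*15\t10\t94775367\tA\tC\trs17882687
"""

CYP2C9_TSV = """gene\tallele\tchrom\tpos\tref\talt\trsid
CYP2C9\t*2\t10\t94942290\tC\tT\trs1799853
CYP2C9\t*61\t10\t94942290\tC\tT\trs1799853
CYP2C9\t*61\t10\t94942309\tA\tG\trs202201137
CYP2C9\t*6\t10\t94981224\tTA\tT\trs9332131
"""

# rsid -> VariantKey lookup over both genes
KEYS = {
    "rs12769205": VariantKey("10", 94762706, "G", "A", "rs12769205"),
    "rs4244285": VariantKey("10", 94781859, "G", "A", "rs4244285"),
    "rs3758581": VariantKey("10", 94842866, "A", "G", "rs3758581"),
    "rs17882687": VariantKey("10", 94775367, "A", "C", "rs17882687"),
    "rs1799853": VariantKey("10", 94942290, "C", "T", "rs1799853"),
    "rs202201137": VariantKey("10", 94942309, "A", "G", "rs202201137"),
    "rs9332131": VariantKey("10", 94981224, "TA", "T", "rs9332131"),
}


@pytest.fixture(scope="session")
def cyp2c19_defs() -> DefinitionSet:
    return parse_definition_table(io.StringIO(CYP2C19_TSV))["CYP2C19"]


@pytest.fixture(scope="session")
def cyp2c9_defs() -> DefinitionSet:
    return parse_definition_table(io.StringIO(CYP2C9_TSV))["CYP2C9"]


@pytest.fixture(scope="session")
def keys() -> dict[str, VariantKey]:
    return dict(KEYS)


def write_vcf(path, samples, records, phased_format=True):
    """Write a minimal VCF 4.3 file.

    ``records`` is a list of ``(chrom, pos, rsid, ref, alt, gts)`` where
    ``alt`` may be comma-joined for multiallelic records and ``gts`` is one
    GT string per sample (e.g. "1|0").
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        contigs = sorted({r[0] for r in records})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, rsid, ref, alt, gts in sorted(records, key=lambda r: (r[0], r[1])):
            fh.write("\t".join([chrom, str(pos), rsid or ".", ref, alt, ".", "PASS",
                                ".", "GT"] + list(gts)) + "\n")
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf
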