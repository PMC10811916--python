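"""Star-allele definition tables.

A star allele (e.g. CYP2C19*2) is a named haplotype defined by an exact set of
variants. Definitions are loaded from a simple TSV dialect with one row per
defining variant::

    gene	allele	chrom	pos	ref	alt	rsid

The reference allele (conventionally ``*1``) is implicit: it is added to every
gene with an empty defining set. Variant identity is positional —
``(chrom, pos, ref, alt)`` — and the rsid is carried for reporting only.
Chromosome labels are normalised by stripping a leading ``chr`` so both GRCh38
naming dialects are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

__all__ = [
    "VariantKey",
    "AlleleDefinition",
    "DefinitionSet",
    "DefinitionParseError",
    "parse_definition_table",
    "write_definition_table",
    "definition_positions",
]

_ALLELE_RE = re.compile(r"^\*\d+$")

REFERENCE_NAME = "*1"


class DefinitionParseError(ValueError):
    """Raised when a definition table violates the dialect contract."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix (case-insensitive) from a contig label."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant in VCF convention (1-based, anchored indels).

    ``rsid`` is annotation only and excluded from identity/ordering.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        label = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"
        return f"{label} ({self.rsid})" if self.rsid else label


@dataclass(frozen=True)
class AlleleDefinition:
    """One named star allele and its exact set of defining variants."""

    gene: str
    name: str
    defining: frozenset[VariantKey]

    def __post_init__(self) -> None:
        if not _ALLELE_RE.match(self.name):
            raise DefinitionParseError(
                f"malformed allele label {self.name!r} for gene {self.gene}"
            )

    @property
    def is_reference(self) -> bool:
        return not self.defining


@dataclass(frozen=True)
class DefinitionSet:
    """All star-allele definitions for one gene, indexed by allele name."""

    gene: str
    alleles: Mapping[str, AlleleDefinition]
    reference_name: str = REFERENCE_NAME
    version: str = ""

    def __post_init__(self) -> None:
        ref = self.alleles.get(self.reference_name)
        if ref is None or ref.defining:
            raise DefinitionParseError(
                f"{self.gene}: reference allele {self.reference_name} must be "
                "present with an empty defining set"
            )
        seen: dict[tuple[str, int, str, str], VariantKey] = {}
        for a in self.alleles.values():
            for v in a.defining:
                ident = (v.chrom, v.pos, v.ref, v.alt)
                seen.setdefault(ident, v)

    @classmethod
    def reference_only(cls, gene: str, version: str = "") -> "DefinitionSet":
        """A gene with no defined non-reference alleles: only *1."""
        ref = AlleleDefinition(gene, REFERENCE_NAME, frozenset())
        return cls(gene=gene, alleles={REFERENCE_NAME: ref}, version=version)

    @property
    def defined_alleles(self) -> list[AlleleDefinition]:
        """Non-reference alleles, in name order."""
        return [a for n, a in sorted(self.alleles.items()) if n != self.reference_name]

    def n_alleles(self) -> int:
        """Total allele count including the reference."""
        return len(self.alleles)


def _build_definition_set(
    gene: str,
    rows: Iterable[tuple[str, VariantKey]],
    version: str = "",
    reference_name: str = REFERENCE_NAME,
) -> DefinitionSet:
    by_allele: dict[str, set[VariantKey]] = {}
    for allele, key in rows:
        by_allele.setdefault(allele, set()).add(key)
    alleles: dict[str, AlleleDefinition] = {
        reference_name: AlleleDefinition(gene, reference_name, frozenset())
    }
    for name, keys in by_allele.items():
        if name == reference_name:
            raise DefinitionParseError(
                f"{gene}: reference allele {reference_name} may not have defining rows"
            )
        alleles[name] = AlleleDefinition(gene, name, frozenset(keys))
    return DefinitionSet(gene=gene, alleles=alleles, reference_name=reference_name,
                         version=version)


_HEADER = ["gene", "allele", "chrom", "pos", "ref", "alt", "rsid"]


def parse_definition_table(
    stream: IO[str] | str, version: str = ""
) -> dict[str, DefinitionSet]:
    """Parse a definition TSV into one :class:`DefinitionSet` per gene.

    Parameters
    ----------
    stream
        Open text handle or path to a tab-separated file with header
        ``gene allele chrom pos ref alt rsid`` and one row per defining
        variant. A gene listed with zero rows is impossible in this dialect;
        genes absent from the file simply yield no DefinitionSet.
    version
        Free-text provenance recorded on every returned set.

    Raises
    ------
    DefinitionParseError
        On duplicate ``(gene, allele, chrom, pos)`` rows, conflicting
        ref/alt for the same ``(chrom, pos, rsid)``, malformed allele
        labels, or a bad header.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream, "rt", encoding="utf-8")
        close = True
    try:
        header_line = stream.readline()
        header = header_line.rstrip("\n").split("\t")
        if header != _HEADER:
            raise DefinitionParseError(
                f"expected header {_HEADER}, got {header}"
            )
        rows_by_gene: dict[str, list[tuple[str, VariantKey]]] = {}
        seen_cell: set[tuple[str, str, str, int]] = set()
        by_site: dict[tuple[str, int, str], tuple[str, str]] = {}
        for lineno, line in enumerate(stream, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise DefinitionParseError(
                    f"line {lineno}: expected 7 tab-separated fields, got {len(fields)}"
                )
            gene, allele, chrom, pos_s, ref, alt, rsid = fields
            chrom = normalize_chrom(chrom)
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise DefinitionParseError(f"line {lineno}: bad pos {pos_s!r}") from exc
            cell = (gene, allele, chrom, pos)
            if cell in seen_cell:
                raise DefinitionParseError(
                    f"line {lineno}: duplicate defining row for "
                    f"{gene} {allele} at {chrom}:{pos}"
                )
            seen_cell.add(cell)
            if rsid:
                site = (chrom, pos, rsid)
                prev = by_site.get(site)
                if prev is not None and prev != (ref, alt):
                    raise DefinitionParseError(
                        f"line {lineno}: conflicting ref/alt for {rsid} at "
                        f"{chrom}:{pos}: {prev} vs {(ref, alt)}"
                    )
                by_site[site] = (ref, alt)
            try:
                key = VariantKey(chrom, pos, ref, alt, rsid)
            except ValueError as exc:
                raise DefinitionParseError(f"line {lineno}: {exc}") from exc
            rows_by_gene.setdefault(gene, []).append((allele, key))
        return {
            gene: _build_definition_set(gene, rows, version=version)
            for gene, rows in rows_by_gene.items()
        }
    finally:
        if close:
            stream.close()


def write_definition_table(defsets: Mapping[str, DefinitionSet], stream: IO[str]) -> None:
    """Serialise definition sets back to the TSV dialect (round-trip safe)."""
    stream.write("\t".join(_HEADER) + "\n")
    for gene in sorted(defsets):
        ds = defsets[gene]
        for allele in ds.defined_alleles:
            for key in sorted(allele.defining):
                stream.write(
                    "\t".join(
                        [gene, allele.name, key.chrom, str(key.pos),
                         key.ref, key.alt, key.rsid]
                    )
                    + "\n"
                )


def definition_positions(defs: DefinitionSet) -> list[VariantKey]:
    """Sorted unique union of all defining variants across a gene's alleles.

    Order is deterministic: ``(chrom, pos, ref, alt)``.
    """
    union: set[VariantKey] = set()
    for allele in defs.alleles.values():
        union |= allele.defining
    return sorted(union)
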