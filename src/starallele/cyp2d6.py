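"""Ingestion of external CYP2D6 caller output (Cyrius-style tables).

CYP2D6 diplotypes come from a dedicated copy-number-aware caller, not from
phased-VCF matching. A call is retained only when the caller flags it as a
passing, unique match to a named allele: ``Filter == "PASS"`` **and**
``Call_info == "unique_match"`` (case-sensitive exact comparisons — these are
literal flag values). Every other row — ``more_than_one_match``,
``pick_common_allele``, non-PASS filters — maps to an ambiguous diplotype,
keeping the sample visible rather than silently dropped (a flag allows
dropping instead). Retained genotype strings are trusted verbatim; the caller
is authoritative for CYP2D6 copy-number content and is not re-validated
against the definition table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import IO, Iterable

from .matcher import AMB, EXTERNAL_CYP2D6, DiplotypeCall, HaplotypeCall

__all__ = ["ExternalCyp2d6Record", "read_cyp2d6_table", "ingest_cyp2d6"]

_GENE = "CYP2D6"
_TSV_HEADER = ["Sample", "Genotype", "Filter", "Call_info", "Raw_star_allele"]
_TOKEN_RE = re.compile(r"^\*\S+$")


@dataclass(frozen=True)
class ExternalCyp2d6Record:
    """One caller output row, fields stored verbatim."""

    sample: str
    genotype: str
    filter: str
    call_info: str
    raw_star_allele: str = ""

    def __post_init__(self) -> None:
        if not self.sample:
            raise ValueError("sample must be non-empty")


class Cyp2d6ParseError(ValueError):
    pass


def read_cyp2d6_table(stream: IO[str] | str) -> list[ExternalCyp2d6Record]:
    """Read caller output as TSV (Cyrius-style header) or JSON-lines.

    TSV columns: ``Sample Genotype Filter Call_info Raw_star_allele``.
    JSON-lines objects use the same keys (case-insensitive).
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream, "rt", encoding="utf-8")
        close = True
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    records: list[ExternalCyp2d6Record] = []
    if lines[0].lstrip().startswith("{"):
        for ln in lines:
            obj = {k.lower(): v for k, v in json.loads(ln).items()}
            records.append(
                ExternalCyp2d6Record(
                    sample=str(obj["sample"]),
                    genotype=str(obj.get("genotype", "")),
                    filter=str(obj.get("filter", "")),
                    call_info=str(obj.get("call_info", "")),
                    raw_star_allele=str(obj.get("raw_star_allele", "")),
                )
            )
        return records
    header = lines[0].split("\t")
    if header != _TSV_HEADER:
        raise Cyp2d6ParseError(f"expected header {_TSV_HEADER}, got {header}")
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != 5:
            raise Cyp2d6ParseError(f"expected 5 fields, got {len(fields)}: {ln!r}")
        records.append(ExternalCyp2d6Record(*fields))
    return records


def _split_genotype(rec: ExternalCyp2d6Record) -> tuple[str, str]:
    g = rec.genotype.replace("×", "x").replace(" ", "")
    parts = g.split("/")
    if len(parts) != 2 or not all(_TOKEN_RE.match(p) for p in parts):
        raise Cyp2d6ParseError(
            f"unparseable genotype {rec.genotype!r} for retained sample {rec.sample}"
        )
    return parts[0], parts[1]


def ingest_cyp2d6(
    records: Iterable[ExternalCyp2d6Record],
    drop_filtered: bool = False,
) -> list[DiplotypeCall]:
    """Map caller rows to diplotype calls under the retention rule.

    A row is retained iff ``filter == "PASS" and call_info == "unique_match"``;
    its genotype string (e.g. ``"*1/*4"`` or ``"*2x2/*10"``) becomes the
    diplotype with source ``EXTERNAL_CYP2D6``. Any other row yields an
    all-ambiguous diplotype whose reason records the rejected class, or is
    omitted entirely when ``drop_filtered`` is true.
    """
    out: list[DiplotypeCall] = []
    for rec in records:
        retained = rec.filter == "PASS" and rec.call_info == "unique_match"
        if retained:
            a1, a2 = _split_genotype(rec)
            h1 = HaplotypeCall(rec.sample, 1, a1, "unique_match")
            h2 = HaplotypeCall(rec.sample, 2, a2, "unique_match")
        elif drop_filtered:
            continue
        else:
            reason = f"filter={rec.filter};call_info={rec.call_info}"
            h1 = HaplotypeCall(rec.sample, 1, AMB, reason)
            h2 = HaplotypeCall(rec.sample, 2, AMB, reason)
        out.append(
            DiplotypeCall(sample=rec.sample, gene=_GENE, hap1=h1, hap2=h2,
                          source=EXTERNAL_CYP2D6)
        )
    return out
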