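"""Diplotype label parsing and call-set concordance scoring.

Benchmark call sets (e.g. GeT-RM consensus tables) print diplotypes in a
variety of notations: phased ``*2|*35``, unordered ``*2/*35``, copy-number
suffixed ``*2 × 2/*10`` (two copies of *2 on one chromosome), tentative calls
wrapped in parentheses ``(*1/*4)``, and tandem arrangements joined with
``+`` such as ``*36/*36 + *10``. :func:`parse_diplotype` normalises all of
these; :func:`compare_callsets` joins two call sets on (sample, gene) and
scores a pair concordant when the unordered multisets of allele tokens (with
copy counts) agree — so phased ``A|B`` always matches unordered ``B/A``.
Tentative reference calls count as concordant when they match.

Because benchmark papers rarely state whether ambiguous calls sit in the
concordance denominator, both policies are first-class: ``COUNT_DISCORDANT``
(default) scores an Amb-containing pair like any other, ``EXCLUDE`` removes
such pairs from the denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

from .matcher import AMB_LABEL, DiplotypeCall, calls_to_frame

__all__ = [
    "AlleleToken",
    "Diplotype",
    "ReferenceCall",
    "ConcordanceResult",
    "parse_diplotype",
    "compare_callsets",
    "DiplotypeParseError",
]

COUNT_DISCORDANT = "COUNT_DISCORDANT"
EXCLUDE = "EXCLUDE"


class DiplotypeParseError(ValueError):
    pass


_PART_RE = re.compile(r"^(\*[A-Za-z0-9.]+?)(?:x(\d+))?$")


@dataclass(frozen=True)
class AlleleToken:
    """One side of a diplotype: one or more (allele, copy-count) parts.

    A plain allele is a single part with copy count 1; ``*2x2`` is one part
    with copy count 2; a ``+``-joined tandem arrangement like ``*36+*10`` is
    a composite of several parts.
    """

    parts: tuple[tuple[str, int], ...]

    @property
    def is_composite(self) -> bool:
        return len(self.parts) > 1

    @property
    def has_copy_gain(self) -> bool:
        return any(n > 1 for _, n in self.parts)

    @property
    def is_amb(self) -> bool:
        return any(name.lower() == AMB_LABEL.lower() for name, _ in self.parts)

    @property
    def name(self) -> str:
        """Allele name of a simple token (first part's name otherwise)."""
        return self.parts[0][0]

    def __str__(self) -> str:
        return "+".join(
            name if n == 1 else f"{name}x{n}" for name, n in self.parts
        )

    def sort_key(self):
        def part_key(part):
            name, n = part
            body = name[1:]
            if body.isdigit():
                return (0, int(body), "", n)
            return (1, 0, body, n)

        return tuple(part_key(p) for p in self.parts)


@dataclass(frozen=True)
class Diplotype:
    """A parsed diplotype label."""

    alleles: tuple[AlleleToken, AlleleToken]
    tentative: bool = False
    separator: str = "/"  # '|' phased, '/' unordered

    def unordered_key(self) -> tuple[str, str]:
        a, b = sorted(self.alleles, key=AlleleToken.sort_key)
        return (str(a), str(b))

    def normalized_label(self) -> str:
        """Unordered slash notation with alleles in ascending order."""
        return "/".join(self.unordered_key())

    @property
    def has_amb(self) -> bool:
        return any(t.is_amb for t in self.alleles)


def _parse_token(text: str, label: str) -> AlleleToken:
    parts = []
    for chunk in text.split("+"):
        m = _PART_RE.match(chunk)
        if not m:
            raise DiplotypeParseError(
                f"unparseable allele token {chunk!r} in diplotype {label!r}"
            )
        name, copies = m.group(1), m.group(2)
        parts.append((name, int(copies) if copies else 1))
    if not parts:
        raise DiplotypeParseError(f"empty allele token in {label!r}")
    return AlleleToken(tuple(parts))


def parse_diplotype(label: str) -> Diplotype:
    """Parse a diplotype label in any of the common printed notations.

    ``×`` is treated as ``x``, whitespace is ignored, a surrounding pair of
    parentheses marks a tentative call, ``|`` marks a phased pair and ``/``
    an unordered one.
    """
    if not label or not label.strip():
        raise DiplotypeParseError("empty diplotype label")
    s = label.replace("×", "x")
    s = re.sub(r"\s+", "", s)
    tentative = False
    if s.startswith("(") and s.endswith(")"):
        tentative = True
        s = s[1:-1]
    if "|" in s:
        sep = "|"
    elif "/" in s:
        sep = "/"
    else:
        raise DiplotypeParseError(f"no '/' or '|' separator in {label!r}")
    halves = s.split(sep)
    if len(halves) != 2:
        raise DiplotypeParseError(f"expected two alleles in {label!r}")
    tokens = tuple(_parse_token(h, label) for h in halves)
    return Diplotype(alleles=tokens, tentative=tentative, separator=sep)


@dataclass(frozen=True)
class ReferenceCall:
    """One row of a reference call set (slash notation, maybe tentative)."""

    sample: str
    gene: str
    diplotype: str

    def parsed(self) -> Diplotype:
        return parse_diplotype(self.diplotype)


@dataclass
class ConcordanceResult:
    n_overlap: int
    n_concordant: int
    n_amb_excluded: int
    percent: float | None
    discordant: list[tuple[str, str, str]] = field(default_factory=list)
    amb_policy: str = COUNT_DISCORDANT

    def summary(self) -> str:
        pct = "NA" if self.percent is None else f"{self.percent:.0f}%"
        lines = [
            f"overlapping (sample, gene) pairs: {self.n_overlap}",
            f"amb-excluded pairs:               {self.n_amb_excluded}",
            f"concordant:                       {self.n_concordant}",
            f"concordance ({self.amb_policy}): {pct}",
        ]
        for sample, a, b in self.discordant:
            lines.append(f"  discordant {sample}: {a} vs {b}")
        return "\n".join(lines)


CallSet = Union[Sequence[DiplotypeCall], pd.DataFrame]


def _as_frame(calls: CallSet) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls
    elif calls and isinstance(calls[0], DiplotypeCall):
        df = calls_to_frame(calls)
    else:
        df = pd.DataFrame(
            [{"sample": c.sample, "gene": c.gene, "diplotype": c.diplotype}
             for c in calls],
            columns=["sample", "gene", "diplotype"],
        )
    missing = {"sample", "gene", "diplotype"} - set(df.columns)
    if missing:
        raise ValueError(f"call set lacks columns: {sorted(missing)}")
    return df[["sample", "gene", "diplotype"]]


def compare_callsets(
    a: CallSet,
    b: CallSet | Iterable[ReferenceCall],
    amb_policy: str = COUNT_DISCORDANT,
) -> ConcordanceResult:
    """Score diplotype-level concordance between two call sets.

    Rows are joined on (sample, gene); only the overlap is scored. A pair is
    concordant iff the unordered multisets of allele tokens agree. Duplicate
    (sample, gene) rows in either input raise ``ValueError``.
    """
    if amb_policy not in (COUNT_DISCORDANT, EXCLUDE):
        raise ValueError(f"unknown amb_policy {amb_policy!r}")
    fa, fb = _as_frame(list(a) if not isinstance(a, pd.DataFrame) else a), \
        _as_frame(list(b) if not isinstance(b, pd.DataFrame) else b)
    for name, f in (("a", fa), ("b", fb)):
        dup = f.duplicated(subset=["sample", "gene"])
        if dup.any():
            keys = f.loc[dup, ["sample", "gene"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (sample, gene) rows in call set {name}: {keys}")
    merged = fa.merge(fb, on=["sample", "gene"], suffixes=("_a", "_b"))
    n_overlap = len(merged)
    n_concordant = 0
    n_amb_excluded = 0
    discordant: list[tuple[str, str, str]] = []
    for row in merged.itertuples(index=False):
        da = parse_diplotype(row.diplotype_a)
        db = parse_diplotype(row.diplotype_b)
        if amb_policy == EXCLUDE and (da.has_amb or db.has_amb):
            n_amb_excluded += 1
            continue
        if da.unordered_key() == db.unordered_key():
            n_concordant += 1
        else:
            discordant.append((row.sample, row.diplotype_a, row.diplotype_b))
    denom = n_overlap - n_amb_excluded
    if denom > 0:
        percent = float(int(100.0 * n_concordant / denom + 0.5))
    else:
        percent = None
    return ConcordanceResult(
        n_overlap=n_overlap,
        n_concordant=n_concordant,
        n_amb_excluded=n_amb_excluded,
        percent=percent,
        discordant=discordant,
        amb_policy=amb_policy,
    )
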