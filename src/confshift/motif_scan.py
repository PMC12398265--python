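"""Amphipathic-motif detection in protein sequence.

Antiphospholipid-syndrome autoantibodies are thought to recognise an
amphipathic surface pattern rather than specific residues: three nonpolar
residues (ϕ), two polar (ζ), a phenylalanine, a spacer, and a final
nonpolar residue — ϕϕϕζζFxϕ, with a cysteine variant ϕϕϕζζFxC and the
class-level simplification ϕϕϕζζϕxϕ.  Because an epitope is a surface, the
pattern is meaningful read in either chain direction.

:func:`scan` is a generic fuzzy class/literal pattern matcher;
:func:`find_epitope_motifs` applies the curated family rule that locates
the five motif sites in the first two domains of β2-glycoprotein I.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import pandas as pd

from confshift.errors import ConfigError, InputError

PHI = "ϕ"  # nonpolar class symbol
ZETA = "ζ"  # polar class symbol
WILDCARD = "x"

#: Default polarity partition.  The published patterns fix only that F and
#: C are nonpolar; the remainder follows the common hydropathy-style split
#: (Gly and Pro counted nonpolar) and can be overridden per scan.
DEFAULT_NONPOLAR = frozenset("AVLIMFWCGP")
DEFAULT_POLAR = frozenset("STNQYHKRDE")


@dataclass(frozen=True)
class ClassAlphabet:
    """Residue -> polarity class mapping over the 20 standard residues."""

    nonpolar: frozenset[str] = DEFAULT_NONPOLAR
    polar: frozenset[str] = DEFAULT_POLAR

    def __post_init__(self) -> None:
        overlap = self.nonpolar & self.polar
        if overlap:
            raise ConfigError(f"residues in both classes: {sorted(overlap)}")
        missing = frozenset("ACDEFGHIKLMNPQRSTVWY") - self.nonpolar - self.polar
        if missing:
            raise ConfigError(f"unclassified residues: {sorted(missing)}")

    def classify(self, residue: str) -> str:
        if residue == "X":
            return WILDCARD
        if residue in self.nonpolar:
            return PHI
        if residue in self.polar:
            return ZETA
        raise ConfigError(f"residue {residue!r} not in alphabet")


DEFAULT_ALPHABET = ClassAlphabet()


def classify_sequence(sequence: str, alphabet: ClassAlphabet = DEFAULT_ALPHABET) -> str:
    """One class symbol (ϕ/ζ, x for unknown X) per residue, order preserved."""
    if not sequence:
        raise InputError("empty sequence")
    return "".join(alphabet.classify(c) for c in sequence.upper())


@dataclass(frozen=True)
class MotifPattern:
    """Pattern over {ϕ, ζ, x} plus literal one-letter residue codes.

    ``x`` matches any residue; with ``x_max`` > 1 each ``x`` may absorb
    1..x_max consecutive residues (the family's spacer is elastic).
    A literal matches only that residue; class symbols match the residue's
    polarity class.  Each failing position adds one mismatch.
    """

    pattern: str
    max_mismatch: int = 0
    directions: str = "both"  # "forward" | "reverse" | "both"
    x_max: int = 1

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise InputError("pattern must have length >= 2")
        if self.directions not in ("forward", "reverse", "both"):
            raise InputError(f"invalid directions {self.directions!r}")
        if self.max_mismatch < 0 or self.x_max < 1:
            raise InputError("max_mismatch >= 0 and x_max >= 1 required")
        for sym in self.pattern:
            if sym not in (PHI, ZETA, WILDCARD) and not sym.isupper():
                raise InputError(f"invalid pattern symbol {sym!r}")


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a pattern on the sequence (1-based inclusive span).

    ``direction`` is 'forward' (pattern read N->C) or 'reverse' (C->N);
    ``variant`` is the observed motif string: literals where the residue
    matches them, class symbols elsewhere, in pattern reading order.
    """

    start: int
    end: int
    direction: str
    mismatches: int
    pattern: str
    variant: str
    classes: str
    x_len: int = 1
    literal_hits: frozenset[str] = field(default_factory=frozenset)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlap(self, other: "MotifMatch") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def _match_at(
    seq: str, classes: str, pattern: str, offset: int, x_lens: tuple[int, ...],
    alphabet: ClassAlphabet,
) -> tuple[int, str, str] | None:
    """Try the pattern at 0-based ``offset`` with the given per-x lengths.
    Returns (mismatches, variant, class string) or None if out of range."""
    pos = offset
    mismatches = 0
    variant = []
    cls_str = []
    xi = 0
    for sym in pattern:
        if sym == WILDCARD:
            ln = x_lens[xi]
            xi += 1
            if pos + ln > len(seq):
                return None
            variant.append(WILDCARD)
            cls_str.append(classes[pos : pos + ln])
            pos += ln
            continue
        if pos >= len(seq):
            return None
        residue = seq[pos]
        cls = classes[pos]
        cls_str.append(cls)
        if sym in (PHI, ZETA):
            ok = cls == sym or cls == WILDCARD
            variant.append(cls if cls != WILDCARD else sym)
        else:  # literal
            ok = residue == sym or residue == "X"
            variant.append(sym if ok else (cls if cls != WILDCARD else sym))
        if not ok:
            mismatches += 1
        pos += 1
    return mismatches, "".join(variant), "".join(cls_str)


def scan(
    sequence: str,
    pattern: MotifPattern,
    alphabet: ClassAlphabet = DEFAULT_ALPHABET,
) -> list[MotifMatch]:
    """All placements of ``pattern`` on ``sequence`` within its mismatch
    budget, in both directions when requested.

    A reverse match reads the pattern C->N; its span is still reported
    low-to-high.  Matches sharing an identical span in both directions are
    deduplicated, keeping the lower-mismatch direction (forward on ties);
    placements at one start differing only in spacer length keep the
    lowest-mismatch, then shortest, alternative.
    """
    seq = sequence.upper()
    if not seq:
        raise InputError("empty sequence")
    if len(pattern.pattern.replace(WILDCARD, "")) + pattern.pattern.count(WILDCARD) \
            > len(seq):
        raise InputError("pattern longer than sequence")
    classes = classify_sequence(seq, alphabet)
    n = len(seq)
    n_x = pattern.pattern.count(WILDCARD)
    directions = (
        ("forward", "reverse") if pattern.directions == "both"
        else (pattern.directions,)
    )
    raw: list[MotifMatch] = []
    for direction in directions:
        s = seq if direction == "forward" else seq[::-1]
        c = classes if direction == "forward" else classes[::-1]
        for x_lens in product(range(1, pattern.x_max + 1), repeat=n_x):
            length = len(pattern.pattern) - n_x + sum(x_lens)
            for offset in range(n - length + 1):
                hit = _match_at(s, c, pattern.pattern, offset, x_lens, alphabet)
                if hit is None:
                    continue
                mism, variant, cls_str = hit
                if mism > pattern.max_mismatch:
                    continue
                if direction == "forward":
                    start, end = offset + 1, offset + length
                else:
                    end = n - offset
                    start = end - length + 1
                literals = frozenset(
                    sym for sym, v in zip(
                        [p for p in pattern.pattern], variant)
                    if sym not in (PHI, ZETA, WILDCARD) and sym == v
                )
                raw.append(
                    MotifMatch(start, end, direction, mism, pattern.pattern,
                               variant, cls_str, max(x_lens) if x_lens else 1,
                               literals)
                )
    return _dedupe(raw)


def _dedupe(matches: list[MotifMatch]) -> list[MotifMatch]:
    best: dict[tuple[int, int], MotifMatch] = {}
    for m in matches:
        key = m.span
        cur = best.get(key)
        if cur is None:
            best[key] = m
            continue
        rank = (m.mismatches, 0 if m.direction == "forward" else 1)
        cur_rank = (cur.mismatches, 0 if cur.direction == "forward" else 1)
        if rank < cur_rank:
            best[key] = m
    # same start, different spacer length: keep lowest mismatch, then shortest
    by_start: dict[tuple[int, str], MotifMatch] = {}
    for m in best.values():
        key = (m.start, m.direction)
        cur = by_start.get(key)
        if cur is None or (m.mismatches, m.end) < (cur.mismatches, cur.end):
            by_start[key] = m
    return sorted(by_start.values(), key=lambda m: (m.start, m.end, m.direction))


# ---------------------------------------------------------------------------
# Curated epitope-motif family search
# ---------------------------------------------------------------------------

#: Core class pattern of the family with an elastic 1-2 residue spacer.
EPITOPE_CORE = MotifPattern(
    pattern=f"{PHI}{PHI}{PHI}{ZETA}{ZETA}{PHI}x{PHI}",
    max_mismatch=3,
    directions="both",
    x_max=2,
)


def _epitope_tier_ok(m: MotifMatch, seq: str) -> bool:
    """Tiered acceptance anchored on the family's literal F/C positions.

    Slot 6 of the core pattern is F in the published patterns and slot 8 is
    C in the cysteine variant; sites carrying both anchors may drift
    furthest from the class consensus (<=3 class mismatches, at most 1 in
    the leading ϕϕϕ block), F-only sites allow one mismatch, C-only sites
    must match the class consensus exactly with the canonical spacer, and
    windows with neither anchor are rejected.
    """
    ordered = seq[m.start - 1 : m.end] if m.direction == "forward" \
        else seq[m.start - 1 : m.end][::-1]
    slot6 = ordered[5]
    slot8 = ordered[-1]
    has_f, has_c = slot6 == "F", slot8 == "C"
    block_mm = sum(
        1 for ch in m.classes[:3] if ch != PHI
    )
    if has_f and has_c:
        return m.mismatches <= 3 and block_mm <= 1
    if has_f:
        return m.mismatches <= 1
    if has_c:
        return m.mismatches == 0 and (m.end - m.start + 1) == 8
    return False


def find_epitope_motifs(
    sequence: str, alphabet: ClassAlphabet = DEFAULT_ALPHABET,
    max_shared_residues: int = 2,
) -> list[MotifMatch]:
    """Locate the amphipathic epitope-motif family in a sequence.

    Scans the elastic class core ϕϕϕζζϕxϕ in both directions, applies the
    literal-anchored acceptance tiers (see :func:`_epitope_tier_ok`), and
    removes redundant placements: candidates are ranked by (mismatches,
    fewer literal anchors, span length, start) and kept only when they
    share at most ``max_shared_residues`` residues with every
    better-ranked kept match.  The ``variant`` strings of the survivors
    reproduce the published motif annotations (e.g. ϕϕϕζζFxC).
    """
    seq = sequence.upper()
    # scan each direction separately: a span may carry its literal anchors
    # only when read one way, and the generic same-span dedup would hide it
    raw = [
        m
        for direction in ("forward", "reverse")
        for m in scan(seq, replace(EPITOPE_CORE, directions=direction), alphabet)
    ]
    # score every candidate against the family literals by re-annotating
    cands = []
    for m in raw:
        if not _epitope_tier_ok(m, seq):
            continue
        ordered = seq[m.start - 1 : m.end] if m.direction == "forward" \
            else seq[m.start - 1 : m.end][::-1]
        n_lit = int(ordered[5] == "F") + int(ordered[-1] == "C")
        variant = _family_variant(ordered, alphabet)
        cands.append((m.mismatches, -n_lit, m.end - m.start, m.start,
                      replace(m, variant=variant)))
    cands.sort(key=lambda t: t[:4])
    kept: list[MotifMatch] = []
    for *_, m in cands:
        if all(m.overlap(k) <= max_shared_residues for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: m.start)


def _family_variant(ordered: str, alphabet: ClassAlphabet) -> str:
    out = []
    for i, residue in enumerate(ordered):
        if i == 5 and residue == "F":
            out.append("F")
        elif i == len(ordered) - 1 and residue == "C":
            out.append("C")
        elif 6 <= i < len(ordered) - 1:
            if i == 6:
                out.append(WILDCARD)  # elastic spacer collapses to one x
        else:
            out.append(alphabet.classify(residue))
    return "".join(out)


def motif_report(
    matches: list[MotifMatch],
    exposure_delta: pd.DataFrame,
    regions,
    rmsf=None,
) -> pd.DataFrame:
    """Join motif matches with their regions' exposure deltas and RMSF trend.

    Each match is paired with every region of ``regions`` that fully
    contains it; the exposure table's rows for that region are attached.
    When ``rmsf`` (an :class:`confshift.dynamics.RmsfWindows`) is given,
    the mean final-window percent RMSF difference over the match residues
    is added; residues absent from the RMSF table raise a join error.
    """
    rows = []
    for m in matches:
        span = set(range(m.start, m.end + 1))
        region_names = [
            name for name in regions.names() if span <= set(regions.residues(name))
        ]
        rmsf_trend = None
        if rmsf is not None:
            missing = sorted(span - set(int(r) for r in rmsf.values.columns))
            if missing:
                raise InputError(
                    f"match {m.span}: residues {missing} missing from RMSF table"
                )
            pct = rmsf.percent_difference()
            rmsf_trend = float(pct.iloc[-1][sorted(span)].mean())
        if not region_names:
            rows.append({"start": m.start, "end": m.end,
                         "direction": m.direction, "variant": m.variant,
                         "mismatches": m.mismatches, "region": None,
                         "rmsf_trend_pct": rmsf_trend})
            continue
        for name in region_names:
            sub = exposure_delta[exposure_delta["region"] == name]
            if sub.empty:
                rows.append({"start": m.start, "end": m.end,
                             "direction": m.direction, "variant": m.variant,
                             "mismatches": m.mismatches, "region": name,
                             "rmsf_trend_pct": rmsf_trend})
            for rec in sub.to_dict("records"):
                rows.append({
                    "start": m.start, "end": m.end, "direction": m.direction,
                    "variant": m.variant, "mismatches": m.mismatches,
                    "region": name, "cluster": rec.get("cluster"),
                    "group": rec.get("group"),
                    "pct_diff_vs_reference": rec.get("pct_diff_vs_reference"),
                    "pct_diff_sem": rec.get("pct_diff_sem"),
                    "rmsf_trend_pct": rmsf_trend,
                })
    return pd.DataFrame(rows)
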