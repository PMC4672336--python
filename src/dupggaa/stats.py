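"""Enrichment statistics for duplicated-motif presence across sequence sets.

Presence of the motif is a per-sequence Bernoulli outcome; sets of promoters
are compared with the exact conditional (Fisher) test, computed here directly
from the hypergeometric mass function with exact integer arithmetic.  Two
calculators predict the expected presence rate of a pattern under an i.i.d.
base-composition background: a Poisson (Chen-Stein flavoured) closed form and
an exact automaton-based computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .nulls import BASES, CompositionModel
from .scan import MotifPattern


def percent_round(n_present: int, n_total: int) -> float:
    """Percentage rounded half-up to 1 decimal (30/58 -> 51.7, 47/58 -> 81.0)."""
    pct = Decimal(100 * n_present) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_percent(value: float) -> str:
    """Render a percentage in table style: trailing '.0' suppressed."""
    s = f"{value:.1f}"
    return s[:-2] if s.endswith(".0") else s


@dataclass(frozen=True)
class PresenceSummary:
    """Presence count, percentage and 95% Wilson interval for one sequence set."""

    set_label: str
    n_total: int
    n_present: int
    percent_present: float
    ci_low: float
    ci_high: float

    def render_cell(self) -> str:
        """'81 (47)' style cell: percent with count in parenthesis."""
        return f"{render_percent(self.percent_present)} ({self.n_present})"

    @property
    def n_absent(self) -> int:
        return self.n_total - self.n_present


def summarize_presence(
    presence: Union[pd.Series, Mapping[str, bool], Iterable[bool]],
    set_label: str = "",
) -> PresenceSummary:
    """Aggregate per-sequence presence calls into a summary row."""
    if isinstance(presence, Mapping):
        values = [bool(v) for v in presence.values()]
    elif isinstance(presence, pd.Series):
        values = [bool(v) for v in presence]
    else:
        values = [bool(v) for v in presence]
    n_total = len(values)
    if n_total == 0:
        raise ValueError("presence table is empty")
    n_present = sum(values)
    lo, hi = proportion_confint(n_present, n_total, alpha=0.05, method="wilson")
    # clamp numerical noise so the interval always contains the point
    # estimate and degenerates exactly at 0/n and n/n
    phat = n_present / n_total
    lo = 0.0 if n_present == 0 else min(float(lo), phat)
    hi = 1.0 if n_present == n_total else max(float(hi), phat)
    return PresenceSummary(
        set_label, n_total, n_present, percent_round(n_present, n_total),
        float(lo), float(hi),
    )


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentComparison:
    """Exact-test comparison of presence between two sets."""

    summary_a: PresenceSummary
    summary_b: PresenceSummary
    odds_ratio: float
    p_two_sided: float
    method: str = "fisher_exact"


def _fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (minimum-likelihood
    convention, relative tie tolerance 1e-12).  Exact integer weights
    C(r1, a') * C(r2, m - a') avoid any floating-point enumeration error.
    """
    r1, r2, m = a + b, c + d, a + c
    if r1 == 0 or r2 == 0:
        raise ValueError("both set sizes (row margins) must be positive")
    n = r1 + r2
    lo, hi = max(0, m - r2), min(r1, m)
    w_obs = math.comb(r1, a) * math.comb(r2, m - a)
    scale = 10**12
    total = 0
    for ap in range(lo, hi + 1):
        w = math.comb(r1, ap) * math.comb(r2, m - ap)
        if w * scale <= w_obs * (scale + 1):
            total += w
    p = Fraction(total, math.comb(n, m))
    return min(1.0, float(p))


def odds_ratio_estimate(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio, with the Haldane-Anscombe 0.5 correction when any
    cell is zero."""
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_exact(
    a_present: int,
    a_absent: int,
    b_present: int,
    b_absent: int,
    labels: tuple[str, str] = ("a", "b"),
) -> EnrichmentComparison:
    """Exact two-sided test of presence between two sets.

    ``a_present``/``a_absent`` are the presence counts of the first set, etc.
    """
    for v in (a_present, a_absent, b_present, b_absent):
        if v < 0:
            raise ValueError("counts must be non-negative")
    p = _fisher_two_sided_p(a_present, a_absent, b_present, b_absent)
    orat = odds_ratio_estimate(a_present, a_absent, b_present, b_absent)
    sa = summarize_presence([True] * a_present + [False] * a_absent, labels[0])
    sb = summarize_presence([True] * b_present + [False] * b_absent, labels[1])
    return EnrichmentComparison(sa, sb, orat, p)


# ---------------------------------------------------------------------------
# Background presence probability
# ---------------------------------------------------------------------------

def expected_match_count(
    model: CompositionModel, length: int, pattern: MotifPattern | None = None
) -> float:
    """Expected number of duplicated-motif matches in an i.i.d. sequence.

    lambda = sum over pair types, spacers s and admissible start positions of
    p(core1) * p(core2), with word probabilities taken from the model.
    """
    if pattern is None:
        pattern = MotifPattern()
    if model.order != 0:
        raise ValueError("closed-form expectation requires an order-0 model; use Monte Carlo")
    words = pattern.words
    lam = 0.0
    for pt in sorted(pattern.effective_pair_types()):
        p_pair = model.word_probability(words[pt[0]]) * model.word_probability(words[pt[1]])
        for s in range(pattern.spacer_min, pattern.spacer_max + 1):
            n_pos = length - 8 - s + 1
            if n_pos > 0:
                lam += n_pos * p_pair
    return lam


def analytic_presence_probability(
    model: CompositionModel, length: int, pattern: MotifPattern | None = None
) -> float:
    """Poisson approximation to the presence probability: P ~= 1 - exp(-lambda).

    Treats match occurrences as independent, which ignores the clumping of
    matches that share a core; the approximation overestimates presence by
    roughly one percentage point at lambda ~= 0.3 and degrades as lambda
    grows.  Use :func:`exact_presence_probability` when exactness matters.
    """
    lam = expected_match_count(model, length, pattern)
    return 1.0 - math.exp(-lam)


@lru_cache(maxsize=64)
def exact_presence_probability(
    model: CompositionModel, length: int, pattern: MotifPattern | None = None
) -> float:
    """Exact probability that an i.i.d. sequence contains >= 1 match.

    Presence is a regular language, so the probability is the absorption mass
    of the pattern automaton run over the length-``length`` i.i.d. base
    process.  The automaton is built lazily by subset construction from the
    union of all (pair type, spacer) word patterns; the faithful default
    yields ~300 states, so the dynamic program is effectively instant.
    """
    if pattern is None:
        pattern = MotifPattern()
    if model.order != 0:
        raise ValueError("exact computation requires an order-0 model; use Monte Carlo")
    key = (
        pattern.core, pattern.spacer_min, pattern.spacer_max,
        tuple(sorted(pattern.effective_pair_types())),
    )
    step = _pattern_automaton(key)
    probs = model.mono_freqs
    dist = {frozenset(): 1.0}
    p_present = 0.0
    for _ in range(length):
        nxt: dict[frozenset, float] = {}
        for state, pr in dist.items():
            for ci, ch in enumerate(BASES):
                ns = step(state, ch)
                w = pr * probs[ci]
                if ns is None:
                    p_present += w
                else:
                    nxt[ns] = nxt.get(ns, 0.0) + w
        dist = nxt
    return p_present


@lru_cache(maxsize=16)
def _pattern_automaton(key):
    """Lazy subset-construction transition function for a pattern union.

    States are frozensets of (pattern index, position) NFA items; ``None``
    denotes the absorbing "match seen" state.  The start items (p, 0) are
    re-seeded at every step, implementing the implicit leading Sigma*.
    """
    core, smin, smax, pair_types = key
    from .io import revcomp

    words = {"F": core, "R": revcomp(core)}
    pats = [
        words[pt[0]] + "." * s + words[pt[1]]
        for pt in pair_types
        for s in range(smin, smax + 1)
    ]
    starts = frozenset((i, 0) for i in range(len(pats)))
    cache: dict = {}

    def step(state, ch):
        k = (state, ch)
        if k in cache:
            return cache[k]
        nxt = set()
        for (i, pos) in state | starts:
            c = pats[i][pos]
            if c == "." or c == ch:
                if pos + 1 == len(pats[i]):
                    cache[k] = None
                    return None
                nxt.add((i, pos + 1))
        r = frozenset(nxt)
        cache[k] = r
        return r

    return step


# ---------------------------------------------------------------------------
# Table-style report
# ---------------------------------------------------------------------------

MOTIF_ROW = "Duplicated GGAA motif"
NO_MOTIF_ROW = "No duplicated GGAA motif"


@dataclass(frozen=True)
class EnrichmentReport:
    """Presence summaries per set plus all pairwise exact-test comparisons."""

    summaries: tuple
    comparisons: tuple

    def render(self) -> str:
        """Plain-text table: one column per set, percent (count) cells."""
        labels = [s.set_label for s in self.summaries]
        rows = [
            [""] + labels,
            [MOTIF_ROW] + [s.render_cell() for s in self.summaries],
            [NO_MOTIF_ROW]
            + [
                f"{render_percent(percent_round(s.n_absent, s.n_total))} ({s.n_absent})"
                for s in self.summaries
            ],
            ["Total"] + [f"100 ({s.n_total})" for s in self.summaries],
        ]
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        lines = [
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
            for row in rows
        ]
        lines.append("")
        for cmp_ in self.comparisons:
            lines.append(
                f"{cmp_.summary_a.set_label} vs {cmp_.summary_b.set_label}: "
                f"OR={cmp_.odds_ratio:.3g}, p={cmp_.p_two_sided:.3g} ({cmp_.method})"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        doc = {
            "sets": [
                {
                    "set_label": s.set_label,
                    "n_total": s.n_total,
                    "n_present": s.n_present,
                    "percent_present": s.percent_present,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
                for s in self.summaries
            ],
            "comparisons": [
                {
                    "a": c.summary_a.set_label,
                    "b": c.summary_b.set_label,
                    "odds_ratio": c.odds_ratio,
                    "p_two_sided": c.p_two_sided,
                    "method": c.method,
                }
                for c in self.comparisons
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                s.set_label: {
                    "n_total": s.n_total,
                    "n_present": s.n_present,
                    "percent_present": s.percent_present,
                }
                for s in self.summaries
            }
        )


def build_table1_report(
    sets: Union[Mapping[str, object], Sequence[tuple[str, object]]],
) -> EnrichmentReport:
    """Build a presence/enrichment report over >= 2 labeled presence tables.

    ``sets`` maps set label -> presence table (Series/dict/iterable of bool).
    Column order follows input order; every pair of sets is compared with the
    exact test.
    """
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    if len(items) < 2:
        raise ValueError("need at least 2 labeled sets to compare")
    summaries = tuple(summarize_presence(tbl, label) for label, tbl in items)
    comparisons = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            sa, sb = summaries[i], summaries[j]
            cmp_ = fisher_exact(
                sa.n_present, sa.n_absent, sb.n_present, sb.n_absent,
                labels=(sa.set_label, sb.set_label),
            )
            comparisons.append(cmp_)
    return EnrichmentReport(summaries, tuple(comparisons))
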