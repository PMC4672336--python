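"""Synthetic promoter sets with planted duplicated GGAA motifs.

Real interferon-stimulated-gene (ISG) promoter panels are study-specific, so
end-to-end testing of the scan -> summarize -> compare pipeline uses labeled
synthetic sets: sequences drawn from a background composition model, a chosen
fraction of which receive exactly one planted core pair at a random position.
Planting overwrites background bases (sequence length is invariant); the
spacer's interior keeps its background bases, since the motif constrains only
the two cores.  Background-borne spontaneous duplications are not suppressed
— as in real promoters, the tabulated statistic is presence, not match count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .io import SequenceRecord, write_fasta
from .nulls import CompositionModel, generate_random_set
from .scan import MotifPattern
from .stats import exact_presence_probability

_PLANT_PAIR_TYPES = ("FF", "FR", "RR")

#: Presence rates of the three-column study design this package emulates:
#: an ISG-like set, a random-gene-like set, and a pure background set.
DEFAULT_TARGET_PRESENCE = (0.81, 0.52)
DEFAULT_SET_SIZES = (58, 58, 60)


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one labeled synthetic set.

    ``plant_rate`` is the probability that a sequence receives one planted
    duplication; ``spacer_weights`` (length spacer_max - spacer_min + 1) and
    ``pair_type_weights`` (over FF, FR, RR) shape the planted motifs.
    """

    n_sequences: int
    plant_rate: float
    length: int = 600
    background: CompositionModel = field(default_factory=CompositionModel.humanized)
    pattern: MotifPattern = field(default_factory=MotifPattern)
    spacer_weights: tuple | None = None
    pair_type_weights: tuple | None = None
    seed: int | None = None
    set_label: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        n_spacers = self.pattern.spacer_max - self.pattern.spacer_min + 1
        sw = self.spacer_weights
        if sw is None:
            sw = (1.0,) * n_spacers
        sw = tuple(float(w) for w in sw)
        if len(sw) != n_spacers or any(w < 0 for w in sw) or sum(sw) == 0:
            raise ValueError(
                f"spacer_weights must be {n_spacers} non-negative weights, not all zero"
            )
        object.__setattr__(self, "spacer_weights", sw)
        pw = self.pair_type_weights
        if pw is None:
            pw = (1.0,) * len(_PLANT_PAIR_TYPES)
        pw = tuple(float(w) for w in pw)
        if len(pw) != len(_PLANT_PAIR_TYPES) or any(w < 0 for w in pw) or sum(pw) == 0:
            raise ValueError("pair_type_weights must be 3 non-negative weights (FF, FR, RR)")
        object.__setattr__(self, "pair_type_weights", pw)
        if self.plant_rate > 0 and self.length < 8 + self.pattern.spacer_max:
            raise ValueError(
                f"length {self.length} cannot hold a planted motif of span "
                f"{8 + self.pattern.spacer_max}"
            )


TRUTH_COLUMNS = ["seq_id", "planted", "start", "end", "spacer", "pair_type"]


def generate_planted_set(spec: PlantSpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate one labeled set plus its ground-truth plant table.

    Returns ``(records, truth)`` where ``truth`` has one row per sequence:
    seq_id, planted flag, and — for planted rows — the 0-based half-open span,
    spacer and sense-view pair type of the written motif.
    """
    ss = np.random.SeedSequence(spec.seed)
    bg_seed, plant_seed = ss.spawn(2)
    records = generate_random_set(
        spec.background, spec.n_sequences, spec.length,
        seed=bg_seed, set_label=spec.set_label, id_prefix=spec.set_label,
    )
    rng = np.random.default_rng(plant_seed)
    words = spec.pattern.words
    spacers = np.arange(spec.pattern.spacer_min, spec.pattern.spacer_max + 1)
    sp_p = np.asarray(spec.spacer_weights) / sum(spec.spacer_weights)
    pt_p = np.asarray(spec.pair_type_weights) / sum(spec.pair_type_weights)
    out: list[SequenceRecord] = []
    rows = []
    for rec in records:
        if rng.random() < spec.plant_rate:
            s = int(rng.choice(spacers, p=sp_p))
            pt = _PLANT_PAIR_TYPES[int(rng.choice(len(_PLANT_PAIR_TYPES), p=pt_p))]
            span = 8 + s
            start = int(rng.integers(0, spec.length - span + 1))
            seq = list(rec.seq)
            seq[start : start + 4] = words[pt[0]]
            seq[start + 4 + s : start + 8 + s] = words[pt[1]]
            out.append(SequenceRecord(rec.id, "".join(seq), spec.set_label))
            rows.append((rec.id, True, start, start + span, s, pt))
        else:
            out.append(rec)
            rows.append((rec.id, False, pd.NA, pd.NA, pd.NA, pd.NA))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return out, truth


def plant_rate_for_presence(
    target_presence: float,
    background: CompositionModel | None = None,
    length: int = 600,
    pattern: MotifPattern | None = None,
) -> float:
    """Plant rate r such that r + (1 - r) * P_bg equals the target presence,
    where P_bg is the exact background presence probability."""
    if background is None:
        background = CompositionModel.humanized()
    p_bg = exact_presence_probability(background, length, pattern)
    if target_presence < p_bg:
        raise ValueError(
            f"target presence {target_presence} below background rate {p_bg:.3f}"
        )
    return (target_presence - p_bg) / (1.0 - p_bg)


@dataclass(frozen=True)
class Table1Scenario:
    """Three labeled synthetic sets mirroring the ISG / random-gene /
    random-sequence column structure, with ground truth."""

    sets: tuple  # of (label, records, truth)
    seed: int | None
    plant_rates: tuple

    def presence_tables(self, pattern: MotifPattern | None = None) -> dict:
        from .scan import scan_set

        return {
            label: scan_set(records, pattern).presence
            for label, records, _ in self.sets
        }

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, records, truth in self.sets:
            write_fasta(records, outdir / f"{label}.fasta", f"seed={self.seed}")
            truth.to_csv(outdir / f"{label}.truth.tsv", sep="\t", index=False)


def make_table1_scenario(
    seed: int | None = None,
    target_presence: tuple[float, float] = DEFAULT_TARGET_PRESENCE,
    set_sizes: tuple[int, int, int] = DEFAULT_SET_SIZES,
    length: int = 600,
    background: CompositionModel | None = None,
) -> Table1Scenario:
    """Build the three-set scenario: ISG-like (high presence), random-gene-like
    (intermediate presence), and pure background.

    Plant rates are derived from the target presence rates by inverting
    expected presence = r + (1 - r) * P_bg against the exact background
    presence probability, so the scenario's expected column percentages match
    the configured targets.
    """
    if background is None:
        background = CompositionModel.humanized()
    rates = tuple(plant_rate_for_presence(t, background, length) for t in target_presence)
    rates = rates + (0.0,)
    labels = ("ISG", "random_gene", "random_seq")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(3)
    sets = []
    for label, n, rate, child_seed in zip(labels, set_sizes, rates, child):
        spec = PlantSpec(
            n_sequences=n, plant_rate=rate, length=length,
            background=background,
            seed=int(child_seed.generate_state(1, dtype=np.uint32)[0] % (2**31)),
            set_label=label,
        )
        records, truth = generate_planted_set(spec)
        sets.append((label, records, truth))
    return Table1Scenario(tuple(sets), seed, rates)
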