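"""Background (null) sequence models: humanized random DNA, random promoter
sampling, and a dinucleotide-preserving shuffle.

"Humanized" random DNA means sequence drawn from a base-composition model
matched to the human genome (GC ~= 0.41).  The default is an i.i.d. (order-0)
model; an order-1 Markov model can be fitted from user-supplied sequence when
dinucleotide structure matters.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .io import SequenceRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class CompositionModel:
    """Mononucleotide (order 0) or first-order Markov base-composition model.

    ``mono_freqs`` orders probabilities as A, C, G, T; for order 1 it doubles
    as the initial-base distribution and ``transition[i][j]`` is
    P(next = base j | current = base i).
    """

    order: int
    mono_freqs: tuple
    transition: tuple | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        mf = np.asarray(self.mono_freqs, dtype=float)
        if mf.shape != (4,) or np.any(mf < 0) or abs(mf.sum() - 1) > 1e-9:
            raise ValueError("mono_freqs must be 4 non-negative probabilities summing to 1")
        object.__setattr__(self, "mono_freqs", tuple(mf))
        if self.order == 1:
            tr = np.asarray(self.transition, dtype=float)
            if tr.shape != (4, 4) or np.any(tr < 0) or np.any(np.abs(tr.sum(axis=1) - 1) > 1e-9):
                raise ValueError("transition must be a 4x4 row-stochastic matrix")
            object.__setattr__(self, "transition", tuple(map(tuple, tr)))
        elif self.transition is not None:
            raise ValueError("order-0 model takes no transition matrix")

    @classmethod
    def humanized(cls) -> "CompositionModel":
        """GC-matched i.i.d. background: A=T=0.295, C=G=0.205 (GC ~= 0.41)."""
        return cls(0, (0.295, 0.205, 0.205, 0.295), label="humanized_gc41")

    @classmethod
    def uniform(cls) -> "CompositionModel":
        return cls(0, (0.25, 0.25, 0.25, 0.25), label="uniform")

    @property
    def gc_fraction(self) -> float:
        return self.mono_freqs[1] + self.mono_freqs[2]

    def word_probability(self, word: str) -> float:
        """Probability of observing ``word`` at a fixed position (stationary
        mono frequencies for order 0; chain product for order 1)."""
        p = self.mono_freqs[_BASE_INDEX[word[0]]]
        for a, b in zip(word, word[1:]):
            if self.order == 0:
                p *= self.mono_freqs[_BASE_INDEX[b]]
            else:
                p *= self.transition[_BASE_INDEX[a]][_BASE_INDEX[b]]
        return p

    def to_json(self) -> dict:
        d = {"order": self.order, "mono_freqs": list(self.mono_freqs), "label": self.label}
        if self.order == 1:
            d["transition"] = [list(r) for r in self.transition]
        return d

    @classmethod
    def from_json(cls, d: dict) -> "CompositionModel":
        return cls(
            d["order"],
            tuple(d["mono_freqs"]),
            tuple(map(tuple, d["transition"])) if d.get("transition") else None,
            d.get("label", ""),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CompositionModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_composition(
    records: Iterable[SequenceRecord], order: int = 0, label: str = "fitted"
) -> CompositionModel:
    """Maximum-likelihood composition fit with add-one smoothing; N excluded.

    Requires at least ``100 * 4**order`` informative (non-N) bases so the
    smoothed estimates are meaningful.
    """
    records = list(records)
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    required = 100 * 4**order
    total = sum(sum(1 for c in r.seq if c in _BASE_INDEX) for r in records)
    if total < required:
        raise ValueError(
            f"insufficient data: {total} non-N bases, need >= {required} for order {order}"
        )
    mono = np.zeros(4)
    for r in records:
        for c in r.seq:
            i = _BASE_INDEX.get(c)
            if i is not None:
                mono[i] += 1
    mono_freqs = tuple((mono + 1) / (mono.sum() + 4))
    if order == 0:
        return CompositionModel(0, mono_freqs, label=label)
    counts = np.zeros((4, 4))
    for r in records:
        for a, b in zip(r.seq, r.seq[1:]):
            i, j = _BASE_INDEX.get(a), _BASE_INDEX.get(b)
            if i is not None and j is not None:
                counts[i, j] += 1
    trans = (counts + 1) / (counts.sum(axis=1, keepdims=True) + 4)
    return CompositionModel(1, mono_freqs, tuple(map(tuple, trans)), label=label)


def generate_random_set(
    model: CompositionModel,
    n: int = 60,
    length: int = 600,
    seed: int | None = None,
    set_label: str = "random_seq",
    id_prefix: str = "rand",
) -> list[SequenceRecord]:
    """Draw ``n`` i.i.d. sequences of ``length`` nt from the model (seeded)."""
    if n < 1 or length < 1:
        raise ValueError("need n >= 1 and length >= 1")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(BASES.encode(), dtype="S1")
    if model.order == 0:
        codes = rng.choice(4, size=(n, length), p=np.asarray(model.mono_freqs))
    else:
        codes = np.empty((n, length), dtype=np.int64)
        codes[:, 0] = rng.choice(4, size=n, p=np.asarray(model.mono_freqs))
        cum = np.cumsum(np.asarray(model.transition), axis=1)
        for t in range(1, length):
            u = rng.random(n)
            rows = cum[codes[:, t - 1]]
            codes[:, t] = (u[:, None] > rows).sum(axis=1)
    width = max(4, len(str(n)))
    return [
        SequenceRecord(
            f"{id_prefix}_{i + 1:0{width}d}",
            letters[codes[i]].tobytes().decode(),
            set_label,
        )
        for i in range(n)
    ]


def sample_promoter_set(
    pool: Sequence[SequenceRecord],
    n: int = 58,
    seed: int | None = None,
    set_label: str = "random_gene",
) -> list[SequenceRecord]:
    """Uniform sample of ``n`` distinct promoters from a pool, without replacement."""
    pool = list(pool)
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [replace(pool[i], set_label=set_label) for i in idx]


def dinucleotide_shuffle(record: SequenceRecord, seed: int | None = None) -> SequenceRecord:
    """Uniform Eulerian-path shuffle preserving exact dinucleotide counts.

    The sequence is viewed as an Eulerian path on the graph whose vertices are
    symbols and whose edges are adjacent pairs.  A random arborescence toward
    the terminal symbol fixes the last exit edge of every other vertex
    (rejection-sampled for connectivity), the remaining out-edges are permuted,
    and the path is re-walked.  First and last symbols — and therefore every
    dinucleotide count — are invariant.  N is treated as a fifth symbol.
    """
    s = record.seq
    if len(s) < 2:
        raise ValueError("dinucleotide shuffle needs length >= 2")
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    sources = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in sources}
        ok = True
        for v in sources:
            cur, hops = v, 0
            while cur != last:
                if cur not in last_edge or hops > len(edges):
                    ok = False
                    break
                cur = last_edge[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break
    queues: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = lst.copy()
        if v != last:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_edge[v])
        queues[v] = rest
    out = [s[0]]
    cur = s[0]
    nxt_idx: dict[str, int] = defaultdict(int)
    for _ in range(len(s) - 1):
        nb = queues[cur][nxt_idx[cur]]
        nxt_idx[cur] += 1
        out.append(nb)
        cur = nb
    return replace(record, seq="".join(out))
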