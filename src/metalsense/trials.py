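"""Trial designs for conjoint measurement (MLCM) and difference scaling
(MLDS), and noisy model observers performing them.

MLCM: every unordered pair of grid conditions (identical pairs included —
they differ by view) is shown ``n_repeats`` times; each trial assigns two
distinct views.  The observer judges which stimulus is more likely to be
made of metal; its decision variable is the difference of an image
statistic plus Gaussian noise.

MLDS: quadruples (a<b<c<d) of levels along one dimension; the observer
judges which pair, (a,b) or (c,d), has the greater within-pair difference
of the statistic, again under Gaussian decision noise.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairTrial",
    "QuadrupleTrial",
    "ModelObserver",
    "enumerate_mlcm_pairs",
    "build_mlcm_session",
    "enumerate_mlds_quadruples",
    "build_mlds_session",
    "simulate_responses",
    "trials_to_dataframe",
    "default_noise_sd",
]


@dataclass
class PairTrial:
    """One conjoint-measurement trial: two (smoothness, bumpiness)
    conditions at two distinct views; response 1 if stimulus 1 was judged
    more metallic."""

    cond_1: tuple[int, int]
    cond_2: tuple[int, int]
    view_1: int
    view_2: int
    repetition: int = 0
    response: int | None = None

    def __post_init__(self) -> None:
        if self.view_1 == self.view_2:
            raise ValueError("views within a trial must differ")


@dataclass
class QuadrupleTrial:
    """One difference-scaling trial along one dimension: four distinct
    levels a<b<c<d at four distinct views; response 1 if pair (a,b) was
    judged the greater within-pair difference."""

    dimension: str  # "smoothness" | "bumpiness"
    levels: tuple[int, int, int, int]
    views: tuple[int, int, int, int]
    response: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.levels)) != 4:
            raise ValueError("all four levels must be distinct")
        if len(set(self.views)) != 4:
            raise ValueError("all four views must be distinct")


@dataclass
class ModelObserver:
    """A noisy observer whose decision variable is a named image statistic
    perturbed by Gaussian noise of standard deviation ``noise_sd``."""

    statistic: str
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def enumerate_mlcm_pairs(
    n_s: int = 5, n_b: int = 5
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All unordered pairs of grid conditions, identical-condition pairs
    included: n(n+1)/2 pairs for n = n_s*n_b conditions (325 for 5x5)."""
    if n_s < 1 or n_b < 1:
        raise ValueError("grid dimensions must be at least 1")
    conds = [(s, b) for s in range(n_s) for b in range(n_b)]
    return list(itertools.combinations_with_replacement(conds, 2))


def build_mlcm_session(
    pairs: Sequence[tuple[tuple[int, int], tuple[int, int]]],
    n_repeats: int = 4,
    n_views: int = 8,
    seed: int = 0,
) -> list[PairTrial]:
    """Repeat every pair ``n_repeats`` times with fresh distinct-view
    assignments and shuffle the order (325 pairs x 4 = 1300 trials)."""
    if n_views < 2:
        raise ValueError("need at least two views")
    rng = np.random.default_rng(seed)
    trials = []
    for rep in range(n_repeats):
        for c1, c2 in pairs:
            v1, v2 = rng.choice(n_views, size=2, replace=False)
            trials.append(
                PairTrial(cond_1=tuple(c1), cond_2=tuple(c2),
                          view_1=int(v1), view_2=int(v2), repetition=rep)
            )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def enumerate_mlds_quadruples(
    n_levels: int = 11,
    rule: str = "nonoverlapping",
    target_count: int | None = None,
    seed: int = 0,
) -> list[tuple[int, int, int, int]]:
    """All non-overlapping quadruples a<b<c<d of ``n_levels`` levels
    (C(11,4) = 330); ``target_count`` uniformly subsamples, reproducibly,
    for designs that used a reduced set (e.g. 310)."""
    if rule != "nonoverlapping":
        raise ValueError(f"unknown quadruple rule {rule!r}")
    quads = list(itertools.combinations(range(n_levels), 4))
    if target_count is not None:
        if not 0 < target_count <= len(quads):
            raise ValueError("target_count out of range")
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(quads), size=target_count, replace=False))
        quads = [quads[i] for i in keep]
    return quads


def build_mlds_session(
    quadruples: Sequence[tuple[int, int, int, int]],
    dimension: str,
    n_views: int = 8,
    seed: int = 0,
) -> list[QuadrupleTrial]:
    """Assign four distinct views to every quadruple and shuffle."""
    if n_views < 4:
        raise ValueError("MLDS trials need at least four views")
    rng = np.random.default_rng(seed)
    trials = [
        QuadrupleTrial(
            dimension=dimension,
            levels=tuple(int(x) for x in q),
            views=tuple(int(v) for v in rng.choice(n_views, size=4, replace=False)),
        )
        for q in quadruples
    ]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


StatTable = Mapping  # (s, b, view) -> value for MLCM; (level, view) for MLDS


def _lookup(table: Mapping, key):
    try:
        return table[key]
    except KeyError as exc:
        raise KeyError(f"statistic table has no entry for {key}") from exc


def simulate_responses(
    trials: Sequence[PairTrial] | Sequence[QuadrupleTrial],
    observer: ModelObserver,
    statistics_table: Mapping,
    statistic_fn: Callable | None = None,
) -> list:
    """Fill in responses of a noisy model observer.

    MLCM (PairTrial): Delta = stat(cond_1, view_1) - stat(cond_2, view_2)
    + eps; respond 1 iff Delta > 0.  MLDS (QuadrupleTrial): Delta =
    |stat(d) - stat(c)| - |stat(b) - stat(a)| + eps; respond 1 (pair (a,b)
    greater) iff Delta < 0.  Exact ties are broken by a fair coin from the
    observer's random stream (reachable only at noise_sd = 0).

    ``statistics_table`` maps (s, b, view) -> value for pair trials, and
    (level, view) -> value for quadruple trials.
    """
    rng = np.random.default_rng(observer.seed)
    out = []
    for t in trials:
        if isinstance(t, PairTrial):
            x1 = _lookup(statistics_table, (*t.cond_1, t.view_1))
            x2 = _lookup(statistics_table, (*t.cond_2, t.view_2))
            delta = x1 - x2 + (rng.normal(0, observer.noise_sd) if observer.noise_sd else 0.0)
            resp = int(delta > 0) if delta != 0 else int(rng.integers(2))
        elif isinstance(t, QuadrupleTrial):
            a, b, c, d = (
                _lookup(statistics_table, (lvl, v))
                for lvl, v in zip(t.levels, t.views)
            )
            delta = abs(d - c) - abs(b - a) + (
                rng.normal(0, observer.noise_sd) if observer.noise_sd else 0.0
            )
            resp = int(delta < 0) if delta != 0 else int(rng.integers(2))
        else:
            raise TypeError(f"unknown trial type {type(t)}")
        out.append(dataclasses.replace(t, response=resp))
    return out


def default_noise_sd(statistics_table: Mapping) -> float:
    """Default simulation noise: 0.1 x the statistic's range over the
    stimulus set, giving recovered d-prime scales of a few units."""
    values = np.asarray(list(statistics_table.values()), dtype=float)
    return 0.1 * float(values.max() - values.min())


def trials_to_dataframe(trials: Sequence) -> pd.DataFrame:
    """Tabular trial export (CSV-ready)."""
    rows = []
    for i, t in enumerate(trials):
        if isinstance(t, PairTrial):
            rows.append(dict(
                trial_id=i, task="mlcm", dim="",
                s1=t.cond_1[0], b1=t.cond_1[1], v1=t.view_1,
                s2=t.cond_2[0], b2=t.cond_2[1], v2=t.view_2,
                repetition=t.repetition, response=t.response,
            ))
        else:
            rows.append(dict(
                trial_id=i, task="mlds", dim=t.dimension,
                a=t.levels[0], b=t.levels[1], c=t.levels[2], d=t.levels[3],
                va=t.views[0], vb=t.views[1], vc=t.views[2], vd=t.views[3],
                response=t.response,
            ))
    return pd.DataFrame(rows)
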