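"""Supervised discretization of continuous risk variables.

Continuous covariates such as age or disease duration relate to event risk
nonlinearly; they are cut into ordinal risk levels by merging
equal-frequency seed bins bottom-up while the Wilson confidence intervals
of adjacent bins' event rates overlap.  Each final bin therefore carries a
statistically distinguishable event rate, an occupancy count and a CI, plus
a nomogram-style score (the bin's log-odds relative to the marginal rate)
consumed by the scoring module.

Interval convention: half-open ``[lo, hi)`` with the last bin closed; a
value equal to a cut point belongs to the upper bin, and out-of-range
values clip to the end bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = ["BinScheme", "event_rate_profile", "supervised_discretize", "bin_assign"]


def _wilson(events: int, n: int, confidence: float) -> tuple[float, float]:
    lo, hi = proportion_confint(events, n, alpha=1.0 - confidence, method="wilson")
    return float(lo), float(hi)


@dataclass
class BinScheme:
    """Ordered bins of one continuous variable with per-bin event statistics."""

    variable: str
    cuts: list[float]  # interior cut points, strictly increasing
    levels: list[dict] = field(default_factory=list)  # count, events, rate, ci, log_odds
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        if self.levels and len(self.levels) != len(self.cuts) + 1:
            raise ValueError("need exactly len(cuts)+1 levels")

    @property
    def n_bins(self) -> int:
        return len(self.cuts) + 1

    def to_json(self, path=None) -> str:
        d = {
            "variable": self.variable,
            "cuts": self.cuts,
            "confidence": self.confidence,
            "interval_convention": "[lo, hi) half-open, last bin closed",
            "levels": self.levels,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, src) -> "BinScheme":
        if isinstance(src, (str, Path)) and Path(str(src)).exists():
            d = json.loads(Path(src).read_text())
        else:
            d = json.loads(src)
        return cls(
            variable=d["variable"],
            cuts=list(map(float, d["cuts"])),
            levels=d["levels"],
            confidence=d.get("confidence", 0.95),
        )


def bin_assign(scheme: BinScheme, x_new) -> np.ndarray:
    """Level index of each value: half-open [lo, hi) bins, ends clipped."""
    x = np.atleast_1d(np.asarray(x_new, dtype=float))
    return np.searchsorted(np.asarray(scheme.cuts), x, side="right")


def event_rate_profile(x, y, grid_size: int = 20, confidence: float = 0.95) -> list[dict]:
    """Equal-width grid over the observed range with per-cell event statistics.

    Returns one dict per cell: lo, hi, count, events, rate and the Wilson CI
    — the numbers behind a density/event-rate strip plot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size == 0:
        raise ValueError("empty input")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # degenerate: all values identical
        n, ev = int(x.size), int(np.sum(y))
        return [{"lo": lo, "hi": hi, "count": n, "events": ev, "rate": ev / n,
                 "ci": _wilson(ev, n, confidence)}]
    edges = np.linspace(lo, hi, grid_size + 1)
    idx = np.clip(np.searchsorted(edges[1:-1], x, side="right"), 0, grid_size - 1)
    cells = []
    for g in range(grid_size):
        mask = idx == g
        n = int(mask.sum())
        ev = int(np.sum(y[mask])) if n else 0
        cells.append({
            "lo": float(edges[g]), "hi": float(edges[g + 1]), "count": n, "events": ev,
            "rate": ev / n if n else float("nan"),
            "ci": _wilson(ev, n, confidence) if n else (float("nan"), float("nan")),
        })
    return cells


def _ci_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def supervised_discretize(
    x,
    y,
    confidence: float = 0.95,
    min_frac: float = 0.05,
    seed_bins: int = 20,
    variable: str = "x",
) -> BinScheme:
    """Cut ``x`` into risk levels by CI-overlap merging of seed bins.

    Equal-frequency seed bins (``seed_bins`` of them) are merged bottom-up:
    while any adjacent pair of bins has overlapping Wilson CIs for the event
    rate, the pair whose pooled two-proportion z statistic is smallest is
    pooled first.  The pairwise CIs use a familywise (Bonferroni-adjusted)
    confidence level across the seed boundaries, so a single noisy seed bin
    is not frozen out once its neighbours have pooled; reported per-level
    CIs are at the nominal confidence.  Afterwards bins holding fewer than
    ``min_frac`` of the rows are folded into the neighbour with the closer
    rate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if not 0.0 < min_frac <= 0.5:
        raise ValueError("min_frac must be in (0, 0.5]")
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be same-length and non-empty")
    n = x.size
    if n * min_frac < 2 or np.unique(x).size < 2:  # two min-size bins impossible
        warnings.warn("too few rows or distinct values for discretization; using a single bin")
        return _finalize(x, y, [], confidence, variable)

    qs = np.quantile(x, np.linspace(0, 1, seed_bins + 1)[1:-1])
    cuts = sorted(set(float(q) for q in qs if x.min() < q <= x.max()))
    cuts = [c for c in cuts if c > x.min()]

    def stats(cuts_):
        idx = np.searchsorted(np.asarray(cuts_), x, side="right")
        out = []
        for b in range(len(cuts_) + 1):
            m = idx == b
            cnt, ev = int(m.sum()), int(np.sum(y[m]))
            out.append((cnt, ev))
        return out

    # drop cuts producing empty bins
    while True:
        st = stats(cuts)
        empty = [b for b, (cnt, _) in enumerate(st) if cnt == 0]
        if not empty or not cuts:
            break
        b = empty[0]
        cuts.pop(min(b, len(cuts) - 1))

    # bottom-up CI-overlap merging at a familywise-adjusted level
    conf_adj = 1.0 - (1.0 - confidence) / max(1, len(cuts))

    def _pooled_z(a: tuple[int, int], b: tuple[int, int]) -> float:
        (na, ea), (nb, eb) = a, b
        pbar = (ea + eb) / (na + nb)
        se = np.sqrt(max(pbar * (1 - pbar), 1e-12) * (1 / na + 1 / nb))
        return abs(ea / na - eb / nb) / se

    def merge_pass(cuts_: list[float]) -> list[float]:
        while cuts_:
            st = stats(cuts_)
            cis = [_wilson(ev, cnt, conf_adj) for cnt, ev in st]
            candidates = [
                (_pooled_z(st[b], st[b + 1]), b)
                for b in range(len(st) - 1)
                if _ci_overlap(cis[b], cis[b + 1])
            ]
            if not candidates:
                break
            _, b = min(candidates)
            cuts_.pop(b)
        return cuts_

    def refine_pass(cuts_: list[float]) -> list[float]:
        # move each surviving cut to the position maximizing the contrast
        # between its two flanking bins (fixes cuts straddling a change point)
        edges = [-np.inf] + cuts_ + [np.inf]
        out = []
        for b in range(len(cuts_)):
            lo, hi = edges[b], edges[b + 2]
            seg = np.sort(x[(x > lo) & (x <= hi)]) if np.isfinite(lo) else np.sort(x[x <= hi])
            best = (0.0, cuts_[b])
            for q in np.quantile(seg, np.linspace(0.05, 0.95, 37)):
                left = (x > lo) & (x < q) if np.isfinite(lo) else x < q
                right = (x >= q) & (x <= hi) if np.isfinite(hi) else x >= q
                na, nb = int(left.sum()), int(right.sum())
                if na < 10 or nb < 10:
                    continue
                z = _pooled_z((na, int(y[left].sum())), (nb, int(y[right].sum())))
                if z > best[0]:
                    best = (z, float(q))
            out.append(best[1])
        return sorted(set(out))

    cuts = merge_pass(cuts)
    for _ in range(2):
        if not cuts:
            break
        refined = refine_pass(cuts)
        if refined == cuts:
            break
        cuts = merge_pass(refined)

    # enforce per-bin minimum occupancy
    while cuts:
        st = stats(cuts)
        rates = [ev / cnt for cnt, ev in st]
        small = [b for b, (cnt, _) in enumerate(st) if cnt < min_frac * n]
        if not small:
            break
        b = small[0]
        if b == 0:
            cuts.pop(0)
        elif b == len(st) - 1:
            cuts.pop(-1)
        else:
            # fold into the neighbour with the closer event rate
            left = abs(rates[b] - rates[b - 1]) <= abs(rates[b] - rates[b + 1])
            cuts.pop(b - 1 if left else b)

    return _finalize(x, y, cuts, confidence, variable)


def _finalize(x, y, cuts, confidence, variable) -> BinScheme:
    scheme = BinScheme(variable=variable, cuts=list(cuts), confidence=confidence)
    idx = bin_assign(scheme, x)
    marginal = float(np.mean(y))
    base = np.log((marginal + 1e-12) / (1 - marginal + 1e-12))
    levels = []
    for b in range(scheme.n_bins):
        m = idx == b
        cnt, ev = int(m.sum()), int(np.sum(y[m]))
        rate = ev / cnt if cnt else float("nan")
        # smoothed log-odds relative to the marginal rate ("nomogram score")
        lo = np.log((ev + 0.5) / (cnt - ev + 0.5)) - base if cnt else float("nan")
        levels.append({
            "count": cnt, "events": ev, "rate": rate,
            "ci": list(_wilson(ev, cnt, confidence)) if cnt else [float("nan")] * 2,
            "log_odds": float(lo),
        })
    scheme.levels = levels
    return scheme
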