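"""Model/Results objects tying the mark-function machinery together.

:class:`MarkCorrelationAnalysis` is built from a :class:`MarkedPattern` and a
mark choice; ``fit()`` computes the requested mark correlation functions and
their permutation envelopes and returns a :class:`MarkCorrelationResults`
with per-bin estimates, envelope bounds, significance flags, a ``summary()``
table and plotting.  :class:`PlotScaling` does the same for the plot-size
accuracy/precision experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envelopes import EnvelopeConfig, attach_envelopes, build_envelopes
from .geometry import MarkedPattern, normalize_marks
from .markfuncs import (
    MarkFunctionResult,
    f1_nn_mark_mean,
    f1_plan,
    f2_plan,
    f2_schlather,
    f3_density_corr,
    f3_plan,
    f4_aggregation_corr,
    f4_plan,
    make_bins,
)
from .scaling import ScalingConfig, ScalingResult, residual_correlogram, scaling_curve

__all__ = ["MarkCorrelationAnalysis", "MarkCorrelationResults", "PlotScaling", "PlotScalingResults"]

_FUNC_LABELS = {
    "f1": "f1_nn_mean",
    "f2": "f2_schlather",
    "f3": "f3_density",
    "f4": "f4_aggregation",
}


class MarkCorrelationAnalysis:
    """Distance-, density- and aggregation-dependence of one mark.

    Parameters
    ----------
    pattern:
        The marked point pattern.
    mark:
        ``"seed"`` or ``"agb"``.  For AGB, trees without a DBH measurement
        are excluded up front (``n_excluded`` reports how many) and all
        spatial structure is recomputed on the remaining trees.
    use_normalized:
        Analyse concession-normalized marks (default).  Raw marks are
        offered for sensitivity analysis only; between-concession mean
        differences then dominate the statistics.
    """

    def __init__(self, pattern: MarkedPattern, mark: str = "seed", use_normalized: bool = True):
        if mark not in ("seed", "agb"):
            raise ValueError(f"unknown mark {mark!r}")
        self.mark = mark
        self.use_normalized = use_normalized
        if mark == "agb":
            defined = pattern.trees["agb_kg"].notna().to_numpy()
            self.n_excluded = int((~defined).sum())
            if self.n_excluded:
                pattern = MarkedPattern(
                    pattern.trees[defined], {c: w.boundary for c, w in pattern.windows.items()}
                )
        else:
            self.n_excluded = 0
        self.pattern = pattern
        self.n_used = pattern.n_trees
        col = {"seed": "seed_kg", "agb": "agb_kg"}[mark]
        self.marks = (
            normalize_marks(pattern, mark)
            if use_normalized
            else pattern.trees[col].to_numpy(dtype=float)
        )

    def fit(
        self,
        functions=("f1", "f2", "f3", "f4"),
        scheme: str = "near_5",
        radii=None,
        envelope: EnvelopeConfig | None = EnvelopeConfig(),
    ) -> "MarkCorrelationResults":
        """Compute the requested functions, with envelopes unless
        ``envelope=None``.  ``scheme`` applies to f1/f2; ``radii`` (default
        10..350 m step 10) to f3/f4."""
        bins = make_bins(scheme)
        if radii is None:
            radii = make_bins("cumulative").centers
        results: dict[str, MarkFunctionResult] = {}
        dropped = np.nan
        for f in functions:
            if f == "f1":
                res = f1_nn_mark_mean(self.pattern, self.marks, bins, self.mark)
                plan = f1_plan(self.pattern, bins)[0]
                dropped = res.dropped_fraction
            elif f == "f2":
                res = f2_schlather(self.pattern, self.marks, bins, self.mark)
                plan = f2_plan(self.pattern, bins)[0]
                dropped = res.dropped_fraction
            elif f == "f3":
                res = f3_density_corr(self.pattern, self.marks, radii, self.mark)
                plan = f3_plan(self.pattern, radii)[0]
            elif f == "f4":
                res = f4_aggregation_corr(self.pattern, self.marks, radii, self.mark)
                plan = f4_plan(self.pattern, radii)[0]
            else:
                raise ValueError(f"unknown function {f!r}")
            if envelope is not None:
                env = build_envelopes(plan, self.pattern, self.marks, envelope)
                attach_envelopes(res, env)
            results[f] = res
        return MarkCorrelationResults(
            model=self, results=results, scheme=scheme, envelope=envelope, dropped_fraction=dropped
        )


@dataclass
class MarkCorrelationResults:
    model: MarkCorrelationAnalysis
    results: dict
    scheme: str
    envelope: EnvelopeConfig | None
    dropped_fraction: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (function, r)."""
        frames = []
        for key, res in self.results.items():
            t = res.table.copy()
            t.insert(0, "function", res.function)
            t.insert(1, "mark", res.mark)
            t.insert(2, "scheme", res.scheme)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def significant_bins(self, function: str) -> pd.DataFrame:
        return self.results[function].significant_bins()

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Mark correlation analysis of {m.mark} "
            f"({'normalized' if m.use_normalized else 'raw'} marks)",
            f"trees used: {m.n_used}"
            + (f" ({m.n_excluded} excluded, no DBH)" if m.n_excluded else ""),
        ]
        if not np.isnan(self.dropped_fraction):
            lines.append(
                f"nearest-neighbour edge rule dropped {100 * self.dropped_fraction:.1f}% of trees"
            )
        if self.envelope is not None:
            lines.append(
                f"envelopes: {self.envelope.n_sim} mark shuffles, rank {self.envelope.rank} "
                f"(pointwise level {self.envelope.level:.3f}, scope {self.envelope.shuffle_scope})"
            )
        for key, res in self.results.items():
            t = res.table
            nsig = int(t["significant"].fillna(False).sum())
            lines.append(
                f"  {res.function}: {len(t)} bins, {nsig} significant"
                + (f", {int((t['flag'] == 'empty').sum())} empty" if (t["flag"] == "empty").any() else "")
            )
        return "\n".join(lines)

    def plot(self, function: str = "f1", ax=None):
        """Observed statistic (dots; open where significant) with envelope."""
        import matplotlib.pyplot as plt

        res = self.results[function]
        t = res.table
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ref = 1.0 if function == "f1" else 0.0
        ax.axhline(ref, ls="--", c="grey", lw=0.8)
        ax.plot(t["r"], t["envelope_lo"], c="grey", lw=1)
        ax.plot(t["r"], t["envelope_hi"], c="grey", lw=1)
        sig = t["significant"].fillna(False).to_numpy(dtype=bool)
        ax.plot(t["r"][~sig], t["statistic"][~sig], "o", c="black", ms=4)
        ax.plot(t["r"][sig], t["statistic"][sig], "o", mfc="white", mec="black", ms=5)
        ax.set_xlabel("r (m)")
        ax.set_ylabel(res.function)
        ax.set_title(f"{res.function} ({res.mark}, {self.scheme})")
        return ax


class PlotScaling:
    """Accuracy/precision of area-based assessments vs evaluation-plot size."""

    def __init__(self, pattern: MarkedPattern, mark: str = "seed"):
        if mark == "agb":
            defined = pattern.trees["agb_kg"].notna().to_numpy()
            if not defined.all():
                pattern = MarkedPattern(
                    pattern.trees[defined], {c: w.boundary for c, w in pattern.windows.items()}
                )
        self.pattern = pattern
        self.mark = mark

    def fit(self, config: ScalingConfig = ScalingConfig()) -> "PlotScalingResults":
        return PlotScalingResults(self, scaling_curve(self.pattern, self.mark, config))


@dataclass
class PlotScalingResults:
    model: PlotScaling
    result: ScalingResult

    @property
    def table(self) -> pd.DataFrame:
        return self.result.table

    def summary(self) -> str:
        return self.result.summary()

    def correlogram(self, cell_size: float, bin_edges=None, seed: int = 0) -> pd.DataFrame:
        """Residual spatial autocorrelation check at one cell size."""
        cells = self.result.cell_tables[cell_size]
        row = self.table[self.table["cell_size"] == cell_size].iloc[0]
        resid = cells["measured_ha"] - row["slope"] * cells["expected_ha"]
        if bin_edges is None:
            span = max(cells["cx"].max() - cells["cx"].min(), cells["cy"].max() - cells["cy"].min())
            bin_edges = np.linspace(0, span / 2, 11)[1:]
            bin_edges = np.concatenate([[0], bin_edges])
        return residual_correlogram(
            cells[["cx", "cy"]].to_numpy(), resid.to_numpy(), bin_edges, seed=seed
        )

    def plot(self, ax=None):
        """Slope (with 95% CI) and R^2 against cell area, square-root axis."""
        import matplotlib.pyplot as plt

        t = self.table
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = np.sqrt(t["cell_area_ha"])
        ax.axhline(1.0, ls="--", c="grey", lw=0.8)
        ax.errorbar(
            x,
            t["slope"],
            yerr=[t["slope"] - t["slope_lo"], t["slope_hi"] - t["slope"]],
            fmt="o-",
            label="slope (accuracy)",
        )
        ax.plot(x, t["r2"], "s-", label="$R^2$ (precision)")
        ax.set_xlabel("$\\sqrt{\\mathrm{cell\\ area\\ (ha)}}$")
        ax.set_title(f"Plot-size scaling ({self.model.mark})")
        ax.legend()
        return ax
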