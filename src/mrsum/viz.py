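"""Static MR visualizations: scatter, forest, funnel, and leave-one-out.

Every plotting function returns ``(figure, table)`` where the
:class:`PlotTable` holds all numbers the figure draws (points, error bars,
reference lines).  Rendering is a pure function of the table, so figures
can be regenerated from a saved table and the table is the surface for
numerical regression tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats

from .core import MRInput, MRMVInput, ValidationError, make_input, ratio_estimates
from .multivariable import mvivw, predicted_outcome_associations
from .univariable import METHOD_TOKENS, egger, ivw, run_all

__all__ = ["PlotTable", "scatter_plot", "forest_plot", "funnel_plot",
           "loo_table", "loo_plot", "render"]

_COLUMNS = ["label", "x", "x_lo", "x_hi", "y", "y_lo", "y_hi", "kind"]


@dataclass
class PlotTable:
    """Numeric table behind a figure.

    ``data`` has columns label, x, x_lo, x_hi, y, y_lo, y_hi, kind
    (kind in {variant, method, pooled, reference}); ``metadata`` carries the
    plot type, axis labels, and reference-line definitions
    (dicts with either slope/intercept or a vertical ``x``).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        frame = self.data.copy()
        for key, val in self.metadata.items():
            if isinstance(val, (str, int, float)):
                frame.attrs[key] = val
        frame.to_csv(path, index=False)


def _zq(alpha: float) -> float:
    return float(stats.norm.ppf(1 - alpha / 2))


# --------------------------------------------------------------------------
# scatter
# --------------------------------------------------------------------------


def scatter_plot(data: MRInput | MRMVInput, line: str = "ivw",
                 alpha: float = 0.05):
    """Scatter of genetic associations.

    Univariable: (bx, by) per variant with error bars in both directions and
    a fitted line (through the origin for IVW, with intercept for Egger, or
    ``line="none"``).  Multivariable: predicted versus observed outcome
    associations from the multivariable IVW fit, with a gradient-1 diagonal
    reference line to expose outliers.
    """
    z = _zq(alpha)
    if isinstance(data, MRMVInput):
        fit = mvivw(data, alpha=alpha)
        pred = predicted_outcome_associations(data, fit, alpha)
        rows = pd.DataFrame({
            "label": pred["snp"],
            "x": pred["predicted"],
            "x_lo": pred["predicted_lower"],
            "x_hi": pred["predicted_upper"],
            "y": pred["observed"],
            "y_lo": pred["observed"] - z * pred["observed_se"],
            "y_hi": pred["observed"] + z * pred["observed_se"],
            "kind": "variant",
        })
        meta = {"plot_type": "scatter",
                "xlabel": "Predicted association with outcome",
                "ylabel": f"Association with {data.outcome_name}",
                "lines": [{"slope": 1.0, "intercept": 0.0, "label": "identity"}]}
        return render(PlotTable(rows, meta)), PlotTable(rows, meta)
    if line not in ("ivw", "egger", "none"):
        raise ValidationError(f"unknown line {line!r}; use ivw, egger, or none")
    rows = pd.DataFrame({
        "label": list(data.snps),
        "x": data.bx,
        "x_lo": data.bx - z * data.bxse,
        "x_hi": data.bx + z * data.bxse,
        "y": data.by,
        "y_lo": data.by - z * data.byse,
        "y_hi": data.by + z * data.byse,
        "kind": "variant",
    })
    lines = []
    if line == "ivw":
        est = ivw(data, alpha=alpha)
        lines.append({"slope": est.estimate, "intercept": 0.0, "label": "IVW"})
    elif line == "egger":
        est = egger(data, alpha=alpha)
        lines.append({"slope": est.estimate, "intercept": est.intercept.estimate,
                      "label": "MR-Egger"})
    meta = {"plot_type": "scatter",
            "xlabel": f"Association with {data.exposure_name}",
            "ylabel": f"Association with {data.outcome_name}",
            "lines": lines}
    table = PlotTable(rows, meta)
    return render(table), table


# --------------------------------------------------------------------------
# forest
# --------------------------------------------------------------------------


def forest_plot(data: MRInput, snp_estimates: bool = True, methods=None,
                alpha: float = 0.05, ordering: str = "input",
                second_order: bool = False, seed: int = 12345,
                iterations: int = 10000):
    """Forest plot of variant-specific ratio estimates and/or pooled
    method estimates.

    Default: one row per variant (ratio estimate with normal-quantile CI on
    the first-order SE; ``second_order=True`` switches SEs) followed by the
    IVW estimate.  ``methods`` selects pooled rows by token (see
    ``METHOD_TOKENS``); with ``snp_estimates=False`` at least one method is
    required.  ``ordering="estimate"`` sorts variant rows by estimate.
    """
    if methods is None:
        methods = [] if not snp_estimates else ["ivw"]
    unknown = [m for m in methods if m not in METHOD_TOKENS]
    if unknown:
        raise ValidationError(
            f"unknown method token(s) {unknown}; valid tokens: {METHOD_TOKENS}")
    if not snp_estimates and not methods:
        raise ValidationError("snp_estimates=False requires at least one method")
    if ordering not in ("input", "estimate"):
        raise ValidationError(f"unknown ordering {ordering!r}")
    z = _zq(alpha)
    frames = []
    if snp_estimates:
        rt = ratio_estimates(data, alpha)
        if not rt["defined"].all():
            warnings.warn("dropping variants with bx=0 from the forest plot")
            rt = rt[rt["defined"]]
        se = rt["se_second"] if second_order else rt["se_first"]
        var_rows = pd.DataFrame({
            "label": rt["snp"],
            "x": rt["ratio"],
            "x_lo": rt["ratio"] - z * se,
            "x_hi": rt["ratio"] + z * se,
            "kind": "variant",
        })
        if ordering == "estimate":
            var_rows = var_rows.sort_values("x", kind="stable")
        frames.append(var_rows)
    if methods:
        estimates = run_all(data, list(methods), seed=seed,
                            iterations=iterations, alpha=alpha)
        meth_rows = pd.DataFrame({
            "label": [_method_label(e) for e in estimates],
            "x": [e.estimate for e in estimates],
            "x_lo": [e.ci_lower for e in estimates],
            "x_hi": [e.ci_upper for e in estimates],
            "kind": "method",
        })
        frames.append(meth_rows)
    rows = pd.concat(frames, ignore_index=True)
    rows["y"] = np.arange(len(rows))[::-1].astype(float)
    rows["y_lo"] = rows["y"]
    rows["y_hi"] = rows["y"]
    rows = rows[_COLUMNS]
    meta = {"plot_type": "forest", "xlabel": "Causal estimate", "ylabel": "",
            "lines": [{"x": 0.0, "label": "null"}]}
    table = PlotTable(rows, meta)
    return render(table), table


_METHOD_LABELS = {"ivw": "IVW", "median": "Simple median",
                  "wmedian": "Weighted median", "pmedian": "Penalized median",
                  "egger": "MR-Egger", "maxlik": "Maximum likelihood",
                  "mbe": "Mode-based", "conmix": "Contamination mixture"}


def _method_label(estimate) -> str:
    return _METHOD_LABELS.get(estimate.method, estimate.method)


# --------------------------------------------------------------------------
# funnel
# --------------------------------------------------------------------------


def funnel_plot(data: MRInput, alpha: float = 0.05):
    """Funnel plot: variant-specific ratio estimates against their precision
    (reciprocal first-order SE), with a vertical reference line at the IVW
    estimate.  Asymmetry suggests directional pleiotropy."""
    z = _zq(alpha)
    rt = ratio_estimates(data, alpha)
    if not rt["defined"].all():
        warnings.warn("dropping variants with bx=0 from the funnel plot")
        rt = rt[rt["defined"]]
    precision = 1.0 / rt["se_first"]
    rows = pd.DataFrame({
        "label": rt["snp"],
        "x": rt["ratio"],
        "x_lo": rt["ratio"] - z * rt["se_first"],
        "x_hi": rt["ratio"] + z * rt["se_first"],
        "y": precision,
        "y_lo": precision,
        "y_hi": precision,
        "kind": "variant",
    })
    est = ivw(data, alpha=alpha)
    meta = {"plot_type": "funnel", "xlabel": "Causal estimate",
            "ylabel": "Precision (1/SE)",
            "lines": [{"x": est.estimate, "label": "IVW"}]}
    table = PlotTable(rows, meta)
    return render(table), table


# --------------------------------------------------------------------------
# leave-one-out
# --------------------------------------------------------------------------


def loo_table(data: MRInput, alpha: float = 0.05) -> PlotTable:
    """Leave-one-out sensitivity table: the IVW estimate omitting each
    variant in turn, plus the full-data IVW estimate as a reference row."""
    J = data.n_variants
    if J < 3:
        raise ValidationError("leave-one-out requires at least 3 variants")
    labels, xs, lo, hi = [], [], [], []
    for j in range(J):
        keep = np.ones(J, dtype=bool)
        keep[j] = False
        sub = make_input(data.bx[keep], data.bxse[keep], data.by[keep],
                         data.byse[keep],
                         snps=[s for s, k in zip(data.snps, keep) if k],
                         exposure_name=data.exposure_name,
                         outcome_name=data.outcome_name)
        est = ivw(sub, alpha=alpha)
        labels.append(data.snps[j])
        xs.append(est.estimate)
        lo.append(est.ci_lower)
        hi.append(est.ci_upper)
    full = ivw(data, alpha=alpha)
    labels.append("All variants")
    xs.append(full.estimate)
    lo.append(full.ci_lower)
    hi.append(full.ci_upper)
    kinds = ["variant"] * J + ["pooled"]
    ypos = np.arange(J + 1)[::-1].astype(float)
    rows = pd.DataFrame({"label": labels, "x": xs, "x_lo": lo, "x_hi": hi,
                         "y": ypos, "y_lo": ypos, "y_hi": ypos, "kind": kinds})
    meta = {"plot_type": "forest", "xlabel": "IVW estimate omitting variant",
            "ylabel": "", "lines": [{"x": full.estimate, "label": "All"}]}
    return PlotTable(rows, meta)


def loo_plot(data: MRInput, alpha: float = 0.05):
    table = loo_table(data, alpha)
    return render(table), table


# --------------------------------------------------------------------------
# rendering (pure function of the table)
# --------------------------------------------------------------------------


def render(table: PlotTable):
    """Draw a figure from a PlotTable alone."""
    from matplotlib.figure import Figure

    plot_type = table.metadata.get("plot_type", "scatter")
    fig = Figure(figsize=(6.4, 4.8))
    ax = fig.add_subplot(111)
    rows = table.data
    if plot_type == "forest":
        for _, row in rows.iterrows():
            color = {"variant": "0.2", "method": "tab:blue",
                     "pooled": "tab:red"}.get(row["kind"], "0.2")
            ax.errorbar(row["x"], row["y"],
                        xerr=[[row["x"] - row["x_lo"]], [row["x_hi"] - row["x"]]],
                        fmt="o", color=color, capsize=2, markersize=3)
        ax.set_yticks(rows["y"])
        ax.set_yticklabels(rows["label"])
        for line in table.metadata.get("lines", []):
            if "x" in line:
                ax.axvline(line["x"], color="0.6", linestyle="--", linewidth=0.8)
    else:  # scatter / funnel
        pts = rows[rows["kind"] == "variant"]
        xerr = np.vstack([pts["x"] - pts["x_lo"], pts["x_hi"] - pts["x"]])
        yerr = np.vstack([pts["y"] - pts["y_lo"], pts["y_hi"] - pts["y"]])
        ax.errorbar(pts["x"], pts["y"], xerr=xerr, yerr=yerr, fmt="o",
                    color="0.2", ecolor="0.6", capsize=2, markersize=3)
        xr = np.array(ax.get_xlim())
        for line in table.metadata.get("lines", []):
            if "slope" in line:
                ax.plot(xr, line["intercept"] + line["slope"] * xr,
                        color="tab:blue", linewidth=1.0, label=line.get("label"))
            elif "x" in line:
                ax.axvline(line["x"], color="tab:blue", linestyle="--",
                           linewidth=0.8, label=line.get("label"))
        if table.metadata.get("lines"):
            ax.legend(loc="best", fontsize=8)
    ax.set_xlabel(table.metadata.get("xlabel", ""))
    ax.set_ylabel(table.metadata.get("ylabel", ""))
    fig.tight_layout()
    return fig
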