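"""Model evaluation and diagnostics.

Emits, per fitted task: variance explained (coefficient of determination,
1 - SS_res/SS_tot) on train/validation/test data per phenotype; the
global-epistasis curve (observed phenotype versus additive trait, with the
model fit); residual-bias checks binned by fitted-value decile; and
per-epoch training traces.  Each diagnostic is written both as a TSV and as
a rendered plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model_fit import GPModel, SplitAssignment


class ReportError(ValueError):
    pass


def variance_explained(y, y_hat) -> float:
    """Proportion of variance explained: R^2 = 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of the observed values.  Note this is the
    coefficient of determination, not squared Pearson correlation; on
    held-out data the two differ.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size:
        raise ReportError("y and y_hat must have equal length")
    if y.size < 2:
        raise ReportError("need at least two observations")
    ss_tot = np.sum(np.square(y - y.mean()))
    if ss_tot == 0:
        raise ReportError("variance explained is undefined for constant y")
    ss_res = np.sum(np.square(y - y_hat))
    return float(1.0 - ss_res / ss_tot)


def performance_summary(
    model: GPModel, splits: SplitAssignment, fold: int
) -> pd.DataFrame:
    """Per-phenotype R^2 for train/validation/test of one fold."""
    labels = splits.labels(fold)
    rows = []
    offset = 0
    for k, table in enumerate(model.dataset.tables):
        y = table.fitness
        y_hat = model.predict_row(k)
        local_labels = labels[offset : offset + table.n]
        offset += table.n
        for split in ("train", "validation", "test"):
            mask = local_labels == split
            n = int(mask.sum())
            r2 = variance_explained(y[mask], y_hat[mask]) if n >= 2 else np.nan
            rows.append(
                {
                    "phenotype": model.dataset.design.rows[k].phenotype,
                    "split": split,
                    "n": n,
                    "r_squared": r2,
                }
            )
    return pd.DataFrame(rows)


def global_epistasis_curve(model: GPModel, phenotype: int = 0) -> pd.DataFrame:
    """Per-variant additive trait value(s), observed and fitted phenotype.

    For bidimensional models the two trait columns are emitted side by side
    (suitable for a surface plot); downstream code may also grid g directly.
    """
    k = phenotype
    phi = model.phi(k)
    y_hat = model.predict_row(k)
    y = model.dataset.tables[k].fitness
    data = {"observed": y, "fitted": y_hat}
    traits = model.traits_of_row(k)
    for j, t in enumerate(traits):
        data[f"phi_{t}"] = phi[:, j]
    return pd.DataFrame(data)


def transformation_surface(
    model: GPModel, phenotype: int = 0, n_grid: int = 41
) -> pd.DataFrame:
    """Grid of g over the observed trait range (1D curve or 2D surface)."""
    k = phenotype
    phi = model.phi(k)
    axes = [
        np.linspace(phi[:, j].min(), phi[:, j].max(), n_grid)
        for j in range(phi.shape[1])
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    p = model.transformations[k].forward(pts, model.theta_g[k])
    scale, shift = model.theta_h[k]
    out = {f"phi_{t}": pts[:, j] for j, t in enumerate(model.traits_of_row(k))}
    out["g"] = p
    out["fitted"] = scale * p + shift
    return pd.DataFrame(out)


def residual_bias_check(y, y_hat, bins: int = 10) -> pd.DataFrame:
    """Mean residual and its standard error per fitted-value decile.

    An adequate global-epistasis model leaves no systematic sign pattern
    across bins.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    res = y - y_hat
    edges = np.quantile(y_hat, np.linspace(0, 1, bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.clip(np.searchsorted(edges, y_hat, side="right") - 1, 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = which == b
        n = int(mask.sum())
        if n == 0:
            rows.append({"bin": b, "n": 0, "mean_residual": np.nan, "sem": np.nan})
            continue
        m = float(res[mask].mean())
        sem = float(res[mask].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "bin": b,
                "n": n,
                "fitted_lo": float(edges[b]),
                "fitted_hi": float(edges[b + 1]),
                "mean_residual": m,
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)


# -- report directory ---------------------------------------------------------


def write_report(collection, out_dir: str | Path, make_plots: bool = True) -> Path:
    """Write performance.tsv, residuals.tsv, curves.tsv, traces.tsv + plots.

    ``collection`` is a :class:`~dmsfit.project.TaskCollection`.  Headline
    performance is reported from each fold's held-out test data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    perf_frames = []
    for fit in collection.cv_fits:
        df = performance_summary(fit.model, collection.splits, fit.fold)
        df.insert(0, "fold", fit.fold)
        perf_frames.append(df)
    perf = pd.concat(perf_frames, ignore_index=True)
    perf.to_csv(out_dir / "performance.tsv", sep="\t", index=False)

    first = collection.cv_fits[0]
    curves = []
    residuals = []
    for k, row in enumerate(collection.dataset.design.rows):
        c = global_epistasis_curve(first.model, k)
        c.insert(0, "phenotype", row.phenotype)
        curves.append(c)
        r = residual_bias_check(c["observed"], c["fitted"])
        r.insert(0, "phenotype", row.phenotype)
        residuals.append(r)
    curves = pd.concat(curves, ignore_index=True)
    residuals = pd.concat(residuals, ignore_index=True)
    curves.to_csv(out_dir / "curves.tsv", sep="\t", index=False)
    residuals.to_csv(out_dir / "residuals.tsv", sep="\t", index=False)

    traces = pd.concat([f.trace for f in collection.cv_fits], ignore_index=True)
    traces.to_csv(out_dir / "traces.tsv", sep="\t", index=False)

    if make_plots:
        _render_plots(collection, curves, traces, out_dir)
    return out_dir


def _render_plots(collection, curves, traces, out_dir: Path) -> None:
    # (i) loss curves per fold
    fig, ax = plt.subplots(figsize=(5, 4))
    for fold, sub in traces.groupby("fold"):
        ax.plot(sub["epoch"], sub["val_loss"], alpha=0.6, label=f"fold {fold}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("validation loss")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out_dir / "loss_curves.png", dpi=120)
    plt.close(fig)

    # (ii) observed phenotype vs additive trait (unidimensional rows only)
    first = collection.cv_fits[0]
    for k, row in enumerate(collection.dataset.design.rows):
        sub = curves[curves["phenotype"] == row.phenotype]
        phi_cols = [c for c in sub.columns if c.startswith("phi_")]
        fig, ax = plt.subplots(figsize=(5, 4))
        if len(phi_cols) == 1:
            ax.scatter(sub[phi_cols[0]], sub["observed"], s=4, alpha=0.3, label="observed")
            order = np.argsort(sub[phi_cols[0]].to_numpy())
            ax.plot(
                sub[phi_cols[0]].to_numpy()[order],
                sub["fitted"].to_numpy()[order],
                color="red",
                label="model",
            )
            ax.set_xlabel("additive trait")
            ax.set_ylabel("observed phenotype")
            ax.legend()
        else:
            ax.scatter(sub["fitted"], sub["observed"], s=4, alpha=0.3)
            ax.set_xlabel("fitted")
            ax.set_ylabel("observed")
        ax.set_title(row.phenotype)
        fig.tight_layout()
        fig.savefig(out_dir / f"global_epistasis_{row.phenotype}.png", dpi=120)
        plt.close(fig)

        # (iii) predicted vs observed
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(sub["fitted"], sub["observed"], s=4, alpha=0.3)
        lim = [
            min(sub["fitted"].min(), sub["observed"].min()),
            max(sub["fitted"].max(), sub["observed"].max()),
        ]
        ax.plot(lim, lim, color="grey", lw=0.8)
        ax.set_xlabel("predicted")
        ax.set_ylabel("observed")
        ax.set_title(row.phenotype)
        fig.tight_layout()
        fig.savefig(out_dir / f"predicted_vs_observed_{row.phenotype}.png", dpi=120)
        plt.close(fig)

    # (iv) per-epoch WT coefficient traces
    wt_cols = [c for c in traces.columns if c.startswith("wt_")]
    fig, ax = plt.subplots(figsize=(5, 4))
    for fold, sub in traces.groupby("fold"):
        for c in wt_cols:
            ax.plot(sub["epoch"], sub[c], alpha=0.5, lw=0.8)
    ax.set_xlabel("epoch")
    ax.set_ylabel("wild-type term")
    fig.tight_layout()
    fig.savefig(out_dir / "wt_traces.png", dpi=120)
    plt.close(fig)
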