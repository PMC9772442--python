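"""Model diagnostics: population/individual predictions, conditional
weighted residuals, and normalized prediction distribution errors.

CWRES uses the FOCEI linearisation quantities: with ``G = df/deta`` at the
eta mode, ``C = G Omega G' + diag(h)`` and the linearised residual
``r = y - f(eta) + G eta``, the conditional weighted residuals are
``C^(-1/2) r`` (symmetric inverse square root).  With all IIV switched off
and a purely proportional error model this reduces exactly to
``(y - f) / (sigma * f)``.

NPDE is fully simulation-based: K population replicates are drawn under the
model (new etas and new residuals; design, doses and covariates fixed at
the observed ones), each subject's observed and simulated vectors are
decorrelated with the inverse Cholesky factor of the empirical simulation
covariance, and the rank of the decorrelated observation among its
decorrelated replicates is mapped through the standard-normal quantile
function.  Exact zero/one ranks are clamped to 1/(2K) and 1 - 1/(2K).
If the model is right, the npde sample is standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .data import ANALYTE_NAME, Dataset
from .engine import Design
from .estimate import FitOptions, FitResult, FoceiEvaluator, ModelSpec
from .errors import ValidationError


@dataclass
class GofTable:
    """Tidy goodness-of-fit table: one row per retained observation."""

    df: pd.DataFrame  # subject, analyte, time, tad, dv, pred, ipred, cwres

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class NpdeResult:
    """Per-observation npde values and global summary checks."""

    df: pd.DataFrame  # subject, analyte, time, tad, dv, pred, npde
    mean: float
    variance: float
    t_statistic: float
    t_pvalue: float
    shapiro_statistic: float
    shapiro_pvalue: float
    n_replicates: int


def _evaluator(dataset: Dataset, model: ModelSpec, design: Design | None):
    if design is None:
        design = Design.from_dataset(dataset)
    return design, FoceiEvaluator(design, model, FitOptions())


def gof_table(
    dataset: Dataset,
    model: ModelSpec,
    fit_result: FitResult | None = None,
    design: Design | None = None,
) -> GofTable:
    """PRED, IPRED and CWRES per retained observation.

    ``fit_result`` supplies the estimates and empirical-Bayes etas; when
    omitted the model's own parameter values are used and eta modes are
    recomputed.
    """
    if fit_result is not None:
        model = fit_result.model
    design, ev = _evaluator(dataset, model, design)
    etas, _, f_mode, J, _ = ev.eta_modes()
    pred = ev.predict(np.zeros((design.n_subjects, ev.n_eta)))
    h = ev._h(f_mode)
    cwres = np.empty(design.n_obs)
    for s, sl in enumerate(design.subject_slices):
        G = J[sl]
        C = (G * ev.omega2[s]) @ G.T if ev.n_eta else np.zeros((sl.stop - sl.start,) * 2)
        C = C + np.diag(h[sl])
        r = design.y[sl] - f_mode[sl] + (G @ etas[s] if ev.n_eta else 0.0)
        vals, vecs = np.linalg.eigh(C)
        inv_sqrt = (vecs / np.sqrt(np.maximum(vals, 1e-300))) @ vecs.T
        cwres[sl] = inv_sqrt @ r
    df = pd.DataFrame(
        {
            "subject": design.subject_ids[design.obs_subject],
            "analyte": [ANALYTE_NAME[d] for d in design.obs_dvid],
            "time": design.obs_time,
            "tad": design.obs_tad,
            "dv": design.y,
            "pred": pred,
            "ipred": f_mode,
            "cwres": cwres,
        }
    )
    return GofTable(df)


def npde(
    dataset: Dataset,
    model: ModelSpec,
    fit_result: FitResult | None = None,
    k: int = 1000,
    seed: int = 0,
    design: Design | None = None,
) -> NpdeResult:
    """Normalized prediction distribution errors from K model replicates."""
    if k < 100:
        raise ValidationError("need at least 100 simulation replicates")
    if fit_result is not None:
        model = fit_result.model
    design, ev = _evaluator(dataset, model, design)
    rng = np.random.default_rng(seed)
    S, n_eta = design.n_subjects, ev.n_eta
    omega = np.sqrt(ev.omega2) if n_eta else np.empty(0)
    etas = rng.normal(0.0, 1.0, size=(k, S, n_eta)) * omega
    f_rep = ev.predict(etas)
    eps = rng.normal(0.0, 1.0, size=f_rep.shape) * np.sqrt(ev.s2)
    y_rep = f_rep * (1.0 + eps)
    pred = f_rep.mean(axis=0)

    npde_vals = np.empty(design.n_obs)
    y = design.y
    for s, sl in enumerate(design.subject_slices):
        sims = y_rep[:, sl]                       # (k, m)
        mu = sims.mean(axis=0)
        centred = sims - mu
        cov = centred.T @ centred / (k - 1)
        lam = 0.0
        diag_mean = float(np.trace(cov)) / cov.shape[0]
        while True:
            try:
                L = np.linalg.cholesky(
                    cov + lam * diag_mean * np.eye(cov.shape[0])
                )
                break
            except np.linalg.LinAlgError:
                lam = 1e-8 if lam == 0.0 else lam * 100.0
                if lam > 1.0:
                    raise
                warnings.warn(
                    "singular simulation covariance; shrinking toward diagonal"
                )
        d_obs = scipy.linalg.solve_triangular(L, y[sl] - mu, lower=True)
        d_sim = scipy.linalg.solve_triangular(L, centred.T, lower=True)  # (m, k)
        pde = (d_sim < d_obs[:, None]).sum(axis=1) / k
        pde = np.clip(pde, 1.0 / (2.0 * k), 1.0 - 1.0 / (2.0 * k))
        npde_vals[sl] = scipy.stats.norm.ppf(pde)

    t_stat, t_p = scipy.stats.ttest_1samp(npde_vals, 0.0)
    sh_stat, sh_p = scipy.stats.shapiro(npde_vals)
    df = pd.DataFrame(
        {
            "subject": design.subject_ids[design.obs_subject],
            "analyte": [ANALYTE_NAME[d] for d in design.obs_dvid],
            "time": design.obs_time,
            "tad": design.obs_tad,
            "dv": design.y,
            "pred": pred,
            "npde": npde_vals,
        }
    )
    return NpdeResult(
        df=df,
        mean=float(npde_vals.mean()),
        variance=float(npde_vals.var(ddof=1)),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        shapiro_statistic=float(sh_stat),
        shapiro_pvalue=float(sh_p),
        n_replicates=k,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_GOF_PANELS = {
    "obs_vs_pred": ["dv", "pred"],
    "obs_vs_ipred": ["dv", "ipred"],
    "cwres_vs_pred": ["pred", "cwres"],
    "cwres_vs_tad": ["tad", "cwres"],
}
_NPDE_PANELS = {
    "npde_qq": ["npde"],
    "npde_hist": ["npde"],
    "npde_vs_time": ["time", "npde"],
    "npde_vs_pred": ["pred", "npde"],
}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    lines = ["\t".join(df.columns)]
    for row in df.itertuples(index=False):
        lines.append("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def diagnostic_export(
    gof: GofTable | None,
    npde_result: NpdeResult | None,
    out_dir: str | Path,
    render: bool = False,
) -> list[Path]:
    """Write one tidy TSV per diagnostic panel per analyte (plus optional
    rendered PNG figures).  Exports are byte-identical for identical
    inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sources = []
    if gof is not None:
        sources.append((gof.df, _GOF_PANELS))
    if npde_result is not None:
        sources.append((npde_result.df, _NPDE_PANELS))
    for df, panels in sources:
        analytes = sorted(df["analyte"].unique()) if len(df) else ["VEN", "ODV"]
        for analyte in analytes:
            sub = df[df["analyte"] == analyte] if len(df) else df
            for panel, cols in panels.items():
                path = out_dir / f"{panel}_{analyte}.tsv"
                _write_tsv(sub[["subject"] + cols] if len(sub) else
                           pd.DataFrame(columns=["subject"] + cols), path)
                written.append(path)
    if render:
        written += _render_figures(gof, npde_result, out_dir)
    return written


def _render_figures(gof, npde_result, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for label, result in (("gof", gof), ("npde", npde_result)):
        if result is None:
            continue
        df = result.df
        for analyte in sorted(df["analyte"].unique()):
            sub = df[df["analyte"] == analyte]
            fig, axes = plt.subplots(2, 2, figsize=(9, 8))
            if label == "gof":
                pairs = [("pred", "dv"), ("ipred", "dv"), ("pred", "cwres"), ("tad", "cwres")]
                for ax, (xc, yc) in zip(axes.ravel(), pairs):
                    ax.plot(sub[xc], sub[yc], "o", ms=3, alpha=0.5)
                    if yc == "cwres":
                        ax.axhline(0.0, color="k", lw=0.8)
                    else:
                        lim = max(sub[xc].max(), sub[yc].max())
                        ax.plot([0, lim], [0, lim], "k-", lw=0.8)
                    ax.set_xlabel(xc)
                    ax.set_ylabel(yc)
            else:
                ax = axes[0, 0]
                scipy.stats.probplot(sub["npde"], dist="norm", plot=ax)
                ax = axes[0, 1]
                ax.hist(sub["npde"], bins=30, density=True, alpha=0.7)
                xs = np.linspace(-4, 4, 200)
                ax.plot(xs, scipy.stats.norm.pdf(xs), "k-")
                for ax, xc in ((axes[1, 0], "time"), (axes[1, 1], "pred")):
                    ax.plot(sub[xc], sub["npde"], "o", ms=3, alpha=0.5)
                    ax.axhline(0.0, color="k", lw=0.8)
                    ax.set_xlabel(xc)
                    ax.set_ylabel("npde")
            fig.suptitle(f"{label.upper()} {analyte}")
            fig.tight_layout()
            path = out_dir / f"{label}_{analyte}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
    return written
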