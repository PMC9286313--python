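"""Per-EV compositional analysis by convex mixing.

Each preprocessed, unit-length EV spectrum is fit as a non-negative,
sum-to-one weighted combination of unit-length component spectra (recovered
by entropy minimization, or ground-truth components in simulation studies).
The equality constraint is enforced through the augmented-row NNLS
formulation with a large weight, followed by exact renormalization onto the
simplex.  Because a unit-length spectrum is a scaled convex combination of
unit-length components, each spectrum is first rescaled onto the affine hull
of the components, which makes the recovered weights scale-invariant and
exact for clean convex mixtures.  Residual norms are recorded but never used
to reject spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import SpectraMatrix


@dataclass
class AbundanceProfile:
    """Convex-mixing weights of one spectrum plus its fit residual."""

    spectrum_id: str
    weights: np.ndarray
    residual_norm: float
    label: str | None = None


@dataclass
class CompositionSummary:
    """Class-level composition: mean weights (pie-chart data) and per-class
    distribution statistics (median, quartiles, 1.5xIQR whiskers)."""

    component_names: list
    means: pd.DataFrame
    medians: pd.DataFrame
    q1: pd.DataFrame
    q3: pd.DataFrame
    whisker_lo: pd.DataFrame
    whisker_hi: pd.DataFrame
    skipped_classes: list


def unit_normalize(m: SpectraMatrix | np.ndarray):
    """Divide every row by its Euclidean norm (vector normalization).

    Raises on all-zero rows, naming the offending row.
    """
    if isinstance(m, SpectraMatrix):
        X = m.intensities
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = m.ids[np.flatnonzero(norms == 0)[0]]
            raise ValueError(f"spectrum {bad!r} is all-zero; cannot normalize")
        return m.with_intensities(X / norms[:, None])
    X = np.atleast_2d(np.asarray(m, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError(
            f"row {int(np.flatnonzero(norms == 0)[0])} is all-zero; "
            "cannot normalize"
        )
    return X / norms[:, None]


def solve_simplex_ls(C: np.ndarray, s: np.ndarray,
                     rho: float | None = None) -> np.ndarray:
    """min ||s - C w||^2 subject to w >= 0 and sum(w) = 1.

    The equality constraint is enforced through the augmented-row NNLS
    formulation with weight ``rho`` (default 1e4 x max|C|), then the solution
    is renormalized exactly onto the simplex.
    """
    if rho is None:
        rho = 1e4 * float(np.abs(C).max())
    A = np.vstack([C, rho * np.ones((1, C.shape[1]))])
    b = np.concatenate([s, [rho]])
    w, _ = nnls(A, b)
    total = w.sum()
    if total <= 0:  # pathological; fall back to the uniform point
        return np.full(C.shape[1], 1.0 / C.shape[1])
    return w / total


def _affine_rescale(C: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale ``s`` so its unconstrained coefficients sum to one.

    A unit-length spectrum is a *scaled* convex combination of unit-length
    components (the norm of a mixture is below one), so fitting the
    sum-to-one model directly to it biases the weights toward the uniform
    point.  Scaling the spectrum onto the affine hull of the components
    first makes the recovered weights scale-invariant and exact for clean
    convex mixtures.
    """
    coeffs, *_ = np.linalg.lstsq(C, s, rcond=None)
    total = coeffs.sum()
    if total > 1e-12:
        return s / total
    return s


def fit_abundances(
    m: SpectraMatrix | np.ndarray,
    components,
    labels=None,
) -> list[AbundanceProfile]:
    """Convex-mixing weights of every spectrum on the given components.

    Both the spectra and the component spectra are unit-length normalized
    before fitting.  ``components`` may be :class:`~evraman.btem.PureComponent`
    objects, :class:`~evraman.synth.ComponentTruth` objects or bare arrays.
    A rank-deficient component set triggers a warning (the solution is then
    non-unique) but a fit is still returned.
    """
    import warnings

    specs, names = [], []
    for i, c in enumerate(components):
        arr = getattr(c, "spectrum", c)
        specs.append(np.asarray(arr, dtype=float))
        names.append(getattr(c, "name", f"component_{i}"))
    if len(specs) < 2:
        raise ValueError("at least two components are required")
    C = unit_normalize(np.vstack(specs)).T  # channels x components

    if np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn(
            "component set is rank-deficient; abundance solution is not unique",
            RuntimeWarning,
        )

    if isinstance(m, SpectraMatrix):
        X = m.intensities
        ids = m.ids
        if labels is None and "label" in m.meta.columns:
            labels = m.labels
    else:
        X = np.atleast_2d(np.asarray(m, dtype=float))
        ids = [f"s{i:05d}" for i in range(X.shape[0])]
    if C.shape[0] != X.shape[1]:
        raise ValueError("components and spectra must share one axis")
    X = unit_normalize(X)

    profiles = []
    for i in range(X.shape[0]):
        s = _affine_rescale(C, X[i])
        w = solve_simplex_ls(C, s)
        resid = float(np.linalg.norm(s - C @ w))
        profiles.append(AbundanceProfile(
            spectrum_id=str(ids[i]), weights=w, residual_norm=resid,
            label=None if labels is None else str(labels[i]),
        ))
    return profiles


def profiles_frame(profiles: list[AbundanceProfile],
                   component_names) -> pd.DataFrame:
    """Tabulate abundance profiles (one row per spectrum)."""
    rows = []
    for p in profiles:
        row = {"id": p.spectrum_id, "label": p.label}
        row.update({f"w_{n}": w for n, w in zip(component_names, p.weights)})
        row["residual_norm"] = p.residual_norm
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_composition(
    profiles: list[AbundanceProfile],
    component_names,
    labels=None,
) -> CompositionSummary:
    """Class-level composition summary (means, medians, IQR whiskers).

    Empty classes (present in ``labels`` but with no profiles) are skipped
    and recorded on the summary.
    """
    if labels is None:
        labels = [p.label for p in profiles]
    if any(lab is None for lab in labels):
        raise ValueError("every profile must carry a class label")
    labels = [str(lab) for lab in labels]
    W = np.vstack([p.weights for p in profiles])
    names = list(component_names)
    classes = list(dict.fromkeys(labels))

    stats = {key: {} for key in ("mean", "median", "q1", "q3", "lo", "hi")}
    kept, skipped = [], []
    arr = np.asarray(labels)
    for c in classes:
        sub = W[arr == c]
        if sub.shape[0] == 0:
            skipped.append(c)
            continue
        kept.append(c)
        q1 = np.percentile(sub, 25, axis=0)
        q3 = np.percentile(sub, 75, axis=0)
        iqr = q3 - q1
        lo = np.array([sub[:, j][sub[:, j] >= q1[j] - 1.5 * iqr[j]].min()
                       for j in range(sub.shape[1])])
        hi = np.array([sub[:, j][sub[:, j] <= q3[j] + 1.5 * iqr[j]].max()
                       for j in range(sub.shape[1])])
        stats["mean"][c] = sub.mean(axis=0)
        stats["median"][c] = np.median(sub, axis=0)
        stats["q1"][c], stats["q3"][c] = q1, q3
        stats["lo"][c], stats["hi"][c] = lo, hi

    def frame(key):
        return pd.DataFrame(
            {c: stats[key][c] for c in kept}, index=names
        ).T

    return CompositionSummary(
        component_names=names, means=frame("mean"), medians=frame("median"),
        q1=frame("q1"), q3=frame("q3"),
        whisker_lo=frame("lo"), whisker_hi=frame("hi"),
        skipped_classes=skipped,
    )


def plot_composition(summary: CompositionSummary, profiles=None,
                     out: str | None = None):
    """Pie charts of per-class mean composition plus per-component violin
    plots of the weight distributions (median as a white point, 1.5xIQR
    whiskers)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    classes = list(summary.means.index)
    names = summary.component_names
    n_comp = len(names)
    fig, axes = plt.subplots(
        2, max(len(classes), n_comp),
        figsize=(3.0 * max(len(classes), n_comp), 6.0),
    )
    axes = np.atleast_2d(axes)
    for i, c in enumerate(classes):
        ax = axes[0, i]
        ax.pie(summary.means.loc[c].to_numpy(), labels=names,
               textprops={"fontsize": 6})
        ax.set_title(str(c), fontsize=8)
    for i in range(len(classes), axes.shape[1]):
        axes[0, i].axis("off")

    if profiles is not None:
        W = np.vstack([p.weights for p in profiles])
        labels = np.asarray([str(p.label) for p in profiles])
        for j, name in enumerate(names):
            ax = axes[1, j]
            data = [W[labels == c, j] for c in classes]
            ax.violinplot(data, showmedians=False, showextrema=False)
            for k, c in enumerate(classes):
                ax.scatter([k + 1], [summary.medians.loc[c].iloc[j]],
                           color="white", edgecolor="black", zorder=3, s=15)
                ax.vlines(k + 1, summary.whisker_lo.loc[c].iloc[j],
                          summary.whisker_hi.loc[c].iloc[j],
                          color="black", lw=1)
            ax.set_title(name, fontsize=8)
            ax.set_xticks(np.arange(1, len(classes) + 1))
            ax.set_xticklabels(classes, rotation=45, fontsize=6)
    for j in range(n_comp, axes.shape[1]):
        axes[1, j].axis("off")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150, metadata={"Software": None})
        plt.close(fig)
        return out
    return fig
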