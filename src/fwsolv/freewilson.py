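"""Ridge-regularized Free-Wilson fit with closed-form leave-one-out CV.

The Free-Wilson model writes a ligand's activity as a scaffold baseline
(intercept) plus one additive contribution per (site, substituent) pair:

    pIC50_i = mu + sum_s beta[s, g_i(s)] + eps_i

Because every level of every site keeps its own indicator column (no
reference level is dropped), the one-hot design is rank-deficient by
construction; an L2 penalty on the coefficients — never on the intercept —
absorbs that.  The penalty strength is selected by exact leave-one-out
cross-validation, computed in closed form from a single SVD of the centered
design: for a linear smoother with hat matrix H, the LOO residual is
``(y_i - yhat_i) / (1 - H_ii)``, which for partially-penalized least squares
(quadratic penalty, unpenalized intercept) is exact, not an approximation.

Identifiability: absolute per-site coefficients are determined only up to an
additive constant per site (shifting all of a site's coefficients by c and
the intercept by -c leaves every prediction unchanged).  Within-site
coefficient *differences* and predictions are identified; interpretation and
recovery tests are phrased in those terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fwsolv.rgroups import DesignMatrix, RGroupAssignment

__all__ = ["FWModel", "fit", "predict", "coefficient_report", "DEFAULT_ALPHA_GRID"]

# 17 log-spaced penalties, 1e-4 .. 1e4
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.logspace(-4, 4, 17))


@dataclass
class FWModel:
    """Fitted additive substituent-contribution model.

    ``coefficients`` maps (site, substituent SMILES) -> contribution in pIC50
    units.  ``alpha`` is the ridge penalty selected by leave-one-out CV from
    ``alpha_grid``; ``loo_mse`` records the LOO mean squared error per grid
    point.  ``r_pearson`` / ``r_squared`` are in-sample; ``loo_r2`` is the
    cross-validated coefficient of determination at the selected alpha.
    Metrics are NaN (``metrics_defined`` False) for a constant response.
    """

    coefficients: dict[tuple[int, str], float]
    intercept: float
    alpha: float
    alpha_grid: tuple[float, ...]
    r_pearson: float
    r_squared: float
    loo_r2: float
    loo_mse: dict[float, float] = field(default_factory=dict)
    metrics_defined: bool = True

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted({s for s, _ in self.coefficients}))

    def site_coefficients(self, site: int) -> dict[str, float]:
        return {g: c for (s, g), c in self.coefficients.items() if s == site}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": self.intercept,
            "alpha": self.alpha,
            "alpha_grid": list(self.alpha_grid),
            "r_pearson": self.r_pearson,
            "r_squared": self.r_squared,
            "loo_r2": self.loo_r2,
            "metrics_defined": self.metrics_defined,
            "coefficients": {
                f"{site}:{sub}": coef for (site, sub), coef in self.coefficients.items()
            },
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FWModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        coefs = {}
        for key, val in payload["coefficients"].items():
            site, sub = key.split(":", 1)
            coefs[(int(site), sub)] = val
        return cls(
            coefficients=coefs,
            intercept=payload["intercept"],
            alpha=payload["alpha"],
            alpha_grid=tuple(payload["alpha_grid"]),
            r_pearson=payload["r_pearson"],
            r_squared=payload["r_squared"],
            loo_r2=payload["loo_r2"],
            metrics_defined=payload.get("metrics_defined", True),
        )


def loo_errors(X: np.ndarray, y: np.ndarray, alphas: Sequence[float]) -> np.ndarray:
    """Exact leave-one-out mean squared error for ridge, one value per alpha.

    Single SVD of the centered design; the intercept is unpenalized and
    enters the hat matrix through the 1/n centering term.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    Uty = U.T @ yc
    out = np.empty(len(alphas))
    for k, alpha in enumerate(alphas):
        d = s**2 / (s**2 + alpha)
        yhat_c = U @ (d * Uty)
        h = 1.0 / n + np.einsum("ij,j,ij->i", U, d, U)
        resid = (yc - yhat_c) / (1.0 - h)
        out[k] = float(np.mean(resid**2))
    return out


def _ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Ridge coefficients and unpenalized intercept (centered formulation)."""
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    beta = Vt.T @ ((s / (s**2 + alpha)) * (U.T @ yc))
    intercept = ybar - float(xbar @ beta)
    return beta, intercept


def fit(
    design: DesignMatrix,
    y: Sequence[float],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
) -> FWModel:
    """Fit the Free-Wilson ridge model, selecting alpha by exact LOO-CV.

    The LOO mean squared error is evaluated on every grid point; the alpha
    minimizing it wins, with ties broken toward the smallest alpha (least
    shrinkage).  Final coefficients are the full-data ridge solution at that
    alpha.  In-sample Pearson r and R^2 are reported; a constant response
    yields intercept = that constant, near-zero coefficients, and undefined
    (NaN) correlation metrics.
    """
    X = np.asarray(design.X, dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = X.shape[0]
    if n != len(y):
        raise ValueError(f"design has {n} rows but y has {len(y)} values")
    if n < 3:
        raise ValueError(f"need at least 3 ligands to fit, got {n}")
    alphas = sorted(float(a) for a in alpha_grid)
    if not alphas or any(a <= 0 for a in alphas):
        raise ValueError("alpha_grid must contain positive values")

    mse = loo_errors(X, y, alphas)
    best = int(np.argmin(mse))  # grid sorted ascending: first argmin = smallest alpha
    alpha = alphas[best]
    beta, intercept = _ridge_solve(X, y, alpha)

    yhat = X @ beta + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    metrics_defined = ss_tot > 0
    if metrics_defined:
        r_squared = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
        r_pearson = float(stats.pearsonr(y, yhat).statistic)
        loo_r2 = 1.0 - mse[best] * n / ss_tot
    else:
        r_squared = r_pearson = loo_r2 = float("nan")

    return FWModel(
        coefficients={key: float(b) for key, b in zip(design.column_index, beta)},
        intercept=float(intercept),
        alpha=alpha,
        alpha_grid=tuple(alphas),
        r_pearson=r_pearson,
        r_squared=r_squared,
        loo_r2=loo_r2,
        loo_mse={a: float(m) for a, m in zip(alphas, mse)},
        metrics_defined=metrics_defined,
    )


def predict(
    model: FWModel, rows: Sequence[Mapping[int, str] | RGroupAssignment]
) -> np.ndarray:
    """Predicted pIC50 for rows of per-site substituents: intercept + sum of coefficients.

    Every (site, substituent) pair must have been seen in training; an unseen
    pair raises with the offending site and group named.
    """
    out = np.empty(len(rows))
    for i, row in enumerate(rows):
        groups = row.groups if isinstance(row, RGroupAssignment) else row
        total = model.intercept
        for site, sub in groups.items():
            try:
                total += model.coefficients[(site, sub)]
            except KeyError:
                raise ValueError(
                    f"substituent {sub!r} at site R{site} was not in the training set"
                ) from None
        out[i] = total
    return out


def coefficient_report(
    model: FWModel, assignments: Sequence[RGroupAssignment] | None = None
) -> pd.DataFrame:
    """Coefficient table: (site, substituent, coefficient, count, effect label).

    Positive coefficients are activity *boosters*, negative are *degraders*.
    With training assignments supplied, each row carries its occurrence count
    and singletons are flagged low-support (a coefficient estimated from one
    molecule).  Sorted by coefficient, descending.
    """
    counts: dict[tuple[int, str], int] = {}
    if assignments:
        for a in assignments:
            if not a.matched:
                continue
            for s, g in a.groups.items():
                counts[(s, g)] = counts.get((s, g), 0) + 1
    rows = []
    for (site, sub), coef in model.coefficients.items():
        n_occ = counts.get((site, sub), 0)
        rows.append(
            {
                "site": site,
                "substituent": sub,
                "coefficient": coef,
                "n_occurrences": n_occ,
                "effect": "booster" if coef > 0 else "degrader",
                "low_support": bool(assignments) and n_occ <= 1,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("coefficient", ascending=False, ignore_index=True)
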