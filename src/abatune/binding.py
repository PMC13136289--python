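"""Tight-binding fluorescence titration analysis.

When receptor concentration is comparable to the dissociation constant,
the free-ligand approximation of the hyperbolic isotherm fails: a
significant fraction of ligand is depleted into complex. The bound
fraction then follows the Morrison (ligand-depletion) quadratic

    [PL]/[P]t = ((Pt + La + Kd) - sqrt((Pt + La + Kd)^2 - 4*Pt*La)) / (2*Pt)

where ``Pt`` is total protein, ``La`` total ligand, and ``Kd`` the
dissociation constant. This is the unique root of the mass-action
equilibrium (Pt - PL)(La - PL) = Kd*PL with 0 <= PL <= min(Pt, La).

Intrinsic tryptophan fluorescence reports occupancy through an affine
signal model F = F0 + dF * fraction_bound, with the amplitude ``dF``
signed: positive for enhancement, negative for quenching. Fitting is
joint over replicates with shared (Kd, F0, dF), multistarted over a
log-spaced Kd grid.

All concentrations are mol/L internally; helpers convert the nM units
used at the bench.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationDataset",
    "BindingFit",
    "fraction_bound",
    "fit_titration",
    "compare_affinities",
    "specificity_report",
]

NM = 1e-9  # mol/L per nanomolar


def fraction_bound(Pt, La, Kd):
    """Bound receptor fraction under ligand depletion (Morrison quadratic).

    Parameters are total protein, total ligand and the dissociation
    constant, all in mol/L; ``La`` may be an array. Uses the conjugate
    form 2*La / (b + sqrt(b^2 - 4*Pt*La)), b = Pt + La + Kd, which is
    numerically stable when the canonical numerator would cancel.
    """
    Pt = float(Pt)
    Kd = float(Kd)
    La_arr = np.asarray(La, dtype=float)
    if Pt <= 0:
        raise ValueError(f"protein concentration must be positive, got {Pt}")
    if Kd <= 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    if np.any(La_arr < 0):
        raise ValueError("ligand concentrations must be non-negative")
    b = Pt + La_arr + Kd
    disc = b * b - 4.0 * Pt * La_arr
    disc = np.maximum(disc, 0.0)  # guards rounding at the stoichiometric point
    frac = 2.0 * La_arr / (b + np.sqrt(disc))
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if np.isscalar(La) or np.ndim(La) == 0 else frac


@dataclass
class TitrationDataset:
    """Fluorescence titration points at fixed total protein concentration.

    ``ligand_total`` and ``fluorescence`` are parallel arrays over all
    replicate points; ``replicate`` labels them. Concentrations in mol/L.
    """

    protein_total: float
    ligand_total: np.ndarray
    fluorescence: np.ndarray
    replicate: np.ndarray
    ligand_name: str = "ABA"
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if self.protein_total <= 0:
            raise ValueError("protein_total must be positive")
        if np.any(self.ligand_total < 0):
            raise ValueError("ligand concentrations must be non-negative")
        n = len(self.ligand_total)
        if len(self.fluorescence) != n or len(self.replicate) != n:
            raise ValueError("ligand_total, fluorescence, replicate must align")

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.ligand_total)

    @classmethod
    def from_csv(
        cls,
        path,
        protein_nM: float,
        ligand_name: str = "ABA",
        temperature_C: float | None = None,
    ) -> "TitrationDataset":
        """Read columns ligand_conc_nM, replicate, fluorescence."""
        df = pd.read_csv(path)
        required = {"ligand_conc_nM", "replicate", "fluorescence"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            protein_total=protein_nM * NM,
            ligand_total=df["ligand_conc_nM"].to_numpy() * NM,
            fluorescence=df["fluorescence"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
            ligand_name=ligand_name,
            temperature_C=temperature_C,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand_conc_nM": self.ligand_total / NM,
                "replicate": self.replicate,
                "fluorescence": self.fluorescence,
            }
        )


@dataclass
class BindingFit:
    """Fitted tight-binding parameters with uncertainties and diagnostics."""

    kd: float  # mol/L
    f0: float  # baseline fluorescence, a.u.
    df: float  # signed amplitude; >0 enhancement, <0 quenching
    se: dict  # parameter -> asymptotic standard error
    rss: float
    converged: bool
    n_points: int
    ligand_name: str = "ABA"
    warnings: list = field(default_factory=list)
    bootstrap: dict | None = None

    @property
    def ka(self) -> float:
        """Association constant, L/mol (exact reciprocal of Kd)."""
        return 1.0 / self.kd

    @property
    def ka_1e8(self) -> float:
        """Ka in units of 1e8 L/mol (the scale binding figures print)."""
        return self.ka / 1e8

    @property
    def kd_nM(self) -> float:
        return self.kd / NM

    def report(self) -> dict:
        return {
            "ligand": self.ligand_name,
            "Kd_nM": self.kd_nM,
            "Ka_1e8_L_per_mol": self.ka_1e8,
            "F0": self.f0,
            "dF": self.df,
            "se": dict(self.se),
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
            "warnings": list(self.warnings),
            **({"bootstrap": self.bootstrap} if self.bootstrap else {}),
        }


def _signal(theta: np.ndarray, Pt: float, La: np.ndarray) -> np.ndarray:
    log_kd, f0, df = theta
    return f0 + df * fraction_bound(Pt, La, math.exp(log_kd))


def _fit_once(theta0, Pt, La, F, df_bounds):
    lb = [-np.inf, -np.inf, df_bounds[0]]
    ub = [np.inf, np.inf, df_bounds[1]]
    theta0 = np.clip(theta0, lb, ub)
    return least_squares(
        lambda th: _signal(th, Pt, La) - F,
        theta0,
        bounds=(lb, ub),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )


def fit_titration(
    dataset: TitrationDataset,
    signal_mode: str = "auto",
    bootstrap: int = 0,
    seed: int | None = None,
    n_starts: int = 25,
) -> BindingFit:
    """Fit (Kd, F0, dF) to a titration by multistart nonlinear least squares.

    ``signal_mode`` constrains the amplitude sign: ``"enhancement"`` forces
    dF >= 0, ``"quenching"`` forces dF <= 0, ``"auto"`` leaves it free so
    one code path covers both intensity increase and quenching. Replicates
    are fitted jointly with shared parameters. Kd starts span
    [1e-2, 1e2] x (max ligand) on a log grid; ties in final residual are
    broken toward the smaller Kd. Standard errors are asymptotic (from the
    Jacobian); an optional seeded residual bootstrap adds resampling-based
    errors.
    """
    if signal_mode not in ("auto", "enhancement", "quenching"):
        raise ValueError(f"unknown signal_mode {signal_mode!r}")
    Pt = dataset.protein_total
    La = dataset.ligand_total
    F = dataset.fluorescence
    levels = dataset.levels
    if len(levels) < 4:
        raise ValueError(
            f"need >= 4 distinct ligand levels to fit, got {len(levels)}"
        )
    if 0.0 not in levels:
        raise ValueError("titration must include a zero-ligand baseline")

    df_bounds = {
        "auto": (-np.inf, np.inf),
        "enhancement": (0.0, np.inf),
        "quenching": (-np.inf, 0.0),
    }[signal_mode]

    f0_init = float(np.mean(F[La == 0.0]))
    span = float(np.mean(F[La == La.max()]) - f0_init)
    if signal_mode == "enhancement":
        span = abs(span)
    elif signal_mode == "quenching":
        span = -abs(span)
    if span == 0.0:
        span = float(np.std(F)) or 1.0

    best = None
    kd_grid = np.geomspace(1e-2, 1e2, n_starts) * La.max()
    for kd0 in kd_grid:
        try:
            res = _fit_once(
                np.array([math.log(kd0), f0_init, span]), Pt, La, F, df_bounds
            )
        except Exception:  # pragma: no cover - optimizer edge failures
            continue
        rss = float(2.0 * res.cost)
        kd_hat = math.exp(res.x[0])
        if best is None:
            best = (rss, kd_hat, res)
        else:
            b_rss, b_kd, _ = best
            if rss < b_rss * (1 - 1e-9) or (
                abs(rss - b_rss) <= 1e-9 * max(b_rss, 1e-300) and kd_hat < b_kd
            ):
                best = (rss, kd_hat, res)

    fit_warnings: list[str] = []
    if best is None:
        return BindingFit(
            kd=float("nan"), f0=float("nan"), df=float("nan"), se={},
            rss=float("nan"), converged=False, n_points=len(F),
            ligand_name=dataset.ligand_name,
            warnings=["all optimizer starts failed"],
        )
    rss, kd_hat, res = best
    log_kd, f0_hat, df_hat = res.x
    converged = bool(res.success and np.all(np.isfinite(res.x)))
    if not converged:
        fit_warnings.append("optimizer did not report convergence")

    # asymptotic SEs; delta method maps log-Kd scale to Kd and Ka
    se: dict = {}
    n, p = len(F), 3
    if n > p:
        try:
            J = res.jac
            cov = rss / (n - p) * np.linalg.inv(J.T @ J)
            se_log_kd, se_f0, se_df = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = {
                "kd": kd_hat * se_log_kd,
                "ka": (1.0 / kd_hat) * se_log_kd,
                "f0": se_f0,
                "df": se_df,
            }
        except np.linalg.LinAlgError:
            fit_warnings.append("singular Jacobian; standard errors unavailable")

    frac = fraction_bound(Pt, La[La > 0], kd_hat)
    if frac.size and np.all(frac > 0.95):
        fit_warnings.append(
            "all non-zero ligand points are >95% saturated; Kd poorly identified"
        )
    if abs(df_hat) == 0.0:
        fit_warnings.append("zero fitted amplitude; fit is uninformative")

    boot = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = _signal(res.x, Pt, La)
        resid = F - fitted
        kds, kas = [], []
        for _ in range(bootstrap):
            F_star = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                r = _fit_once(res.x.copy(), Pt, La, F_star, df_bounds)
            except Exception:  # pragma: no cover
                continue
            kds.append(math.exp(r.x[0]))
            kas.append(1.0 / kds[-1])
        if kds:
            kds_arr = np.array(kds)
            boot = {
                "n_resamples": len(kds),
                "kd_se": float(np.std(kds_arr, ddof=1)),
                "kd_ci95": [float(q) for q in np.quantile(kds_arr, [0.025, 0.975])],
                "ka_se": float(np.std(np.array(kas), ddof=1)),
            }

    return BindingFit(
        kd=kd_hat,
        f0=float(f0_hat),
        df=float(df_hat),
        se=se,
        rss=rss,
        converged=converged,
        n_points=n,
        ligand_name=dataset.ligand_name,
        warnings=fit_warnings,
        bootstrap=boot,
    )


def compare_affinities(reference: BindingFit, variant: BindingFit) -> float:
    """Fold ratio Ka_ref / Ka_variant; > 1 means the variant binds more weakly.

    A four-fold reduction for an E657A-like variant and a near ten-fold
    reduction for a Y678A-like variant are the scales seen for the
    ABA-binding-pocket mutants.
    """
    for fit, which in ((reference, "reference"), (variant, "variant")):
        if not fit.converged:
            raise ValueError(f"{which} fit did not converge; refusing the ratio")
    return reference.ka / variant.ka


def specificity_report(
    fits: Mapping[str, BindingFit],
    reference: str = "ABA",
    threshold_fold: float = 100.0,
) -> dict:
    """Classify each ligand as 'specific' or 'residual' binding.

    A ligand whose Ka is at or below Ka(reference)/threshold_fold is
    classified residual (boundary inclusive). The default 100-fold
    threshold separates ~1e9 L/mol specific binding from the ~1e6 L/mol
    residual binding seen for structurally unrelated hormones (IAA, JA).
    """
    if reference not in fits:
        raise ValueError(f"reference ligand {reference!r} missing from fits")
    ka_ref = fits[reference].ka
    out = {}
    for name, fit in fits.items():
        out[name] = "residual" if fit.ka <= ka_ref / threshold_fold else "specific"
    return out
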