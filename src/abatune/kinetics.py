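"""Enzyme kinetics with an allosteric-modulator series.

Phosphodiesterase assay data — product formed over a fixed incubation by a
fixed protein mass at several substrate concentrations — are converted to
specific rates (pmol min^-1 ug^-1) and fitted to the Michaelis-Menten model

    v = Vmax * S / (KM + S)

separately at each modulator (ABA) concentration. Fold changes of Vmax and
KM versus the zero-modulator control quantify modulation, and a
dose-response profile of activities is classified as flat, monotonic, or
biphasic (hormetic: stimulation at low dose, inhibition at high dose).

Statistics mirror bench practice: Welch's unequal-variance t-test for
two-group comparisons, two-way ANOVA (type II sums of squares) with Tukey
HSD and a compact letter display for variant-by-dose layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "RateMeasurement",
    "KineticsDataset",
    "MMFit",
    "ModulatorSeries",
    "DoseResponseProfile",
    "TestResult",
    "to_rate",
    "fit_mm",
    "modulator_series",
    "biphasic_test",
    "welch_t",
    "anova2_tukey",
    "compact_letter_display",
]

UM = 1e-6  # mol/L per micromolar
NM = 1e-9


def to_rate(product_pmol: float, time_min: float, protein_ug: float) -> float:
    """Specific rate pmol·min⁻¹·µg⁻¹ from raw product amount.

    A 20-minute assay with 5 µg protein yielding 119 pmol product runs at
    1.19 pmol·min⁻¹·µg⁻¹.
    """
    if time_min <= 0 or protein_ug <= 0:
        raise ValueError("time_min and protein_ug must be positive")
    if product_pmol < 0:
        raise ValueError("product amount cannot be negative")
    return product_pmol / (time_min * protein_ug)


@dataclass(frozen=True)
class RateMeasurement:
    """One assay point: substrate and modulator concentration plus a rate."""

    substrate: float  # mol/L
    modulator: float  # mol/L; 0 = control
    replicate: int
    rate: float  # pmol/min/ug

    def __post_init__(self) -> None:
        if self.substrate <= 0:
            raise ValueError("substrate concentration must be positive")
        if self.modulator < 0:
            raise ValueError("modulator concentration must be non-negative")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


@dataclass
class KineticsDataset:
    """Long-form table of rate measurements across modulator levels."""

    data: pd.DataFrame  # columns: substrate_M, modulator_M, replicate, rate

    REQUIRED = ("substrate_M", "modulator_M", "replicate", "rate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        if (self.data["substrate_M"] <= 0).any():
            raise ValueError("substrate concentrations must be positive")

    @property
    def modulator_levels(self) -> np.ndarray:
        return np.sort(self.data["modulator_M"].unique())

    def at_level(self, modulator_M: float) -> pd.DataFrame:
        return self.data[self.data["modulator_M"] == modulator_M]

    @classmethod
    def from_csv(cls, path) -> "KineticsDataset":
        """Read assay CSV.

        Columns: substrate_conc_uM, modulator_conc_nM, replicate, and either
        ``rate`` or the raw triple product_pmol, time_min, protein_ug
        (converted through :func:`to_rate`).
        """
        df = pd.read_csv(path)
        for col in ("substrate_conc_uM", "modulator_conc_nM", "replicate"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        if "rate" in df.columns:
            rate = df["rate"].to_numpy(dtype=float)
        else:
            raw = {"product_pmol", "time_min", "protein_ug"}
            if not raw <= set(df.columns):
                raise ValueError(
                    f"{path}: need either 'rate' or columns {sorted(raw)}"
                )
            rate = np.array(
                [
                    to_rate(p, t, m)
                    for p, t, m in zip(
                        df["product_pmol"], df["time_min"], df["protein_ug"]
                    )
                ]
            )
        return cls(
            pd.DataFrame(
                {
                    "substrate_M": df["substrate_conc_uM"].to_numpy(dtype=float) * UM,
                    "modulator_M": df["modulator_conc_nM"].to_numpy(dtype=float) * NM,
                    "replicate": df["replicate"].to_numpy(),
                    "rate": rate,
                }
            )
        )


@dataclass
class MMFit:
    """Michaelis-Menten parameters for one modulator level."""

    vmax: float  # pmol/min/ug
    km: float  # mol/L
    se: dict
    rss: float
    modulator: float  # mol/L
    converged: bool
    n_points: int
    warnings: list = field(default_factory=list)

    @property
    def km_uM(self) -> float:
        return self.km / UM

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.vmax * S / (self.km + S)

    def report(self) -> dict:
        return {
            "modulator_nM": self.modulator / NM,
            "Vmax_pmol_min_ug": self.vmax,
            "KM_uM": self.km_uM,
            "se": dict(self.se),
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
            "warnings": list(self.warnings),
        }


def _hanes_woolf_init(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (Vmax, KM) from the Hanes-Woolf line S/v = S/Vmax + KM/Vmax."""
    mask = v > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(S[mask], S[mask] / v[mask], 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept / slope
    return float(np.max(v)) * 1.2 or 1.0, float(np.median(S))


def fit_mm(
    points: pd.DataFrame | None = None,
    *,
    S=None,
    v=None,
    modulator: float = 0.0,
) -> MMFit:
    """Fit v = Vmax*S/(KM+S) by least squares at one modulator level.

    Accepts either a dataframe with substrate_M and rate columns or raw
    ``S``/``v`` arrays. Requires >= 4 distinct substrate levels.
    Initialization comes from a Hanes-Woolf linearization; standard errors
    from the Jacobian. When the sampled substrate range cannot constrain
    KM (all S far above the fitted KM, or KM error comparable to the
    estimate), an identifiability warning is attached.
    """
    if points is not None:
        if "modulator_M" in points.columns and len(points):
            levels = points["modulator_M"].unique()
            if len(levels) > 1:
                raise ValueError("fit_mm expects a single modulator level")
            modulator = float(levels[0])
        S = points["substrate_M"].to_numpy(dtype=float)
        v = points["rate"].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError(
            f"need >= 4 distinct substrate levels, got {len(np.unique(S))}"
        )

    p0 = _hanes_woolf_init(S, v)
    fit_warnings: list[str] = []
    try:
        popt, pcov = curve_fit(
            lambda s, vm, km: vm * s / (km + s),
            S,
            v,
            p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt, pcov = np.array([np.nan, np.nan]), np.full((2, 2), np.nan)
        converged = False
        fit_warnings.append("Michaelis-Menten fit failed to converge")

    vmax, km = float(popt[0]), float(popt[1])
    resid = v - vmax * S / (km + S) if converged else v
    rss = float(np.sum(resid**2))
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    se = {"vmax": float(perr[0]), "km": float(perr[1])}

    if converged:
        if km > 0 and np.min(S) >= 10.0 * km:
            fit_warnings.append(
                "all substrate concentrations >= 10x fitted KM; "
                "KM is poorly identified"
            )
        if np.isfinite(se["km"]) and km > 0 and se["km"] >= km:
            fit_warnings.append("KM standard error exceeds the estimate")

    return MMFit(
        vmax=vmax,
        km=km,
        se=se,
        rss=rss,
        modulator=modulator,
        converged=converged,
        n_points=len(S),
        warnings=fit_warnings,
    )


@dataclass
class ModulatorSeries:
    """Per-modulator-level MM fits with fold changes versus control."""

    fits: dict  # modulator_M -> MMFit
    percent_vmax_change: dict  # modulator_M -> signed %
    percent_km_change: dict

    @property
    def control(self) -> MMFit:
        return self.fits[0.0]

    def report(self) -> dict:
        return {
            "levels_nM": [m / NM for m in sorted(self.fits)],
            "fits": {f"{m / NM:g}": self.fits[m].report() for m in sorted(self.fits)},
            "percent_vmax_change": {
                f"{m / NM:g}": pc for m, pc in sorted(self.percent_vmax_change.items())
            },
            "percent_km_change": {
                f"{m / NM:g}": pc for m, pc in sorted(self.percent_km_change.items())
            },
        }


def modulator_series(dataset: KineticsDataset) -> ModulatorSeries:
    """Fit every modulator level and express signed percent changes vs control.

    The control is the level with modulator concentration exactly 0; its
    absence is an error. Percent change of Vmax at level m is
    100*(Vmax_m - Vmax_0)/Vmax_0 (signed; +32.8% for a 1.19 -> 1.58 rise).
    """
    levels = dataset.modulator_levels
    if 0.0 not in levels:
        raise ValueError("no control (modulator = 0) level in dataset")
    fits = {float(m): fit_mm(dataset.at_level(m)) for m in levels}
    ctrl = fits[0.0]
    pv, pk = {}, {}
    for m, f in fits.items():
        if m == 0.0:
            pv[m] = 0.0
            pk[m] = 0.0
        else:
            pv[m] = 100.0 * (f.vmax - ctrl.vmax) / ctrl.vmax
            pk[m] = 100.0 * (f.km - ctrl.km) / ctrl.km
    return ModulatorSeries(fits=fits, percent_vmax_change=pv, percent_km_change=pk)


@dataclass
class TestResult:
    """Outcome of a hypothesis test, optionally with post-hoc structure."""

    statistic: float
    df: float | tuple
    pvalue: float
    anova_table: pd.DataFrame | None = None
    pairwise: dict | None = None  # level -> DataFrame of pairwise comparisons
    letters: dict | None = None  # level -> {group: letters}


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df).

    Identical constant groups return t = 0, p = 1 by convention; distinct
    constant groups return p = 0 (infinite evidence at zero variance).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(statistic=0.0, df=float(len(a) + len(b) - 2), pvalue=1.0)
        return TestResult(
            statistic=float("inf") if a.mean() > b.mean() else float("-inf"),
            df=float(len(a) + len(b) - 2),
            pvalue=0.0,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    dof = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return TestResult(statistic=float(res.statistic), df=float(dof), pvalue=float(res.pvalue))


@dataclass
class DoseResponseProfile:
    """Relative activity versus modulator dose with a shape classification."""

    levels: list  # modulator concentrations, control (0) first
    relative_activity: dict  # level -> mean activity / control mean
    tests: pd.DataFrame  # per-level Welch results vs control (raw + adjusted)
    classification: str  # flat | monotonic_up | monotonic_down | biphasic
    alpha: float
    adjust: str

    def report(self) -> dict:
        return {
            "levels": list(self.levels),
            "relative_activity": {f"{k:g}": v for k, v in self.relative_activity.items()},
            "classification": self.classification,
            "alpha": self.alpha,
            "adjust": self.adjust,
            "tests": self.tests.to_dict(orient="records"),
        }


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def biphasic_test(
    activities: Mapping[float, Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "holm",
) -> DoseResponseProfile:
    """Classify a dose-response profile of replicate activities.

    ``activities`` maps modulator concentration (0 = control) to replicate
    activity values. Each dose level is Welch-tested against the control;
    p-values are Holm-adjusted across levels (``adjust="none"`` disables).
    Classification is *biphasic* iff some level is significantly above the
    control and some strictly higher level significantly below it —
    the hormetic low-dose-stimulation / high-dose-inhibition signature.
    Otherwise the sign pattern of significant effects gives monotonic_up,
    monotonic_down, or flat; a mixed pattern that is not low-up/high-down
    falls back to the sign at the highest significant dose.
    """
    if adjust not in ("holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if 0.0 not in activities:
        raise ValueError("control level (0) required")
    doses = sorted(k for k in activities if k != 0.0)
    if len(doses) < 3:
        raise ValueError(f"need >= 3 non-control levels, got {len(doses)}")
    for lvl, vals in activities.items():
        if len(vals) < 2:
            raise ValueError(
                f"level {lvl:g} has a single replicate; variance undefined"
            )
    control = np.asarray(activities[0.0], dtype=float)
    ctrl_mean = control.mean()

    rows = []
    for d in doses:
        vals = np.asarray(activities[d], dtype=float)
        t = welch_t(vals, control)
        rows.append(
            {
                "level": d,
                "mean": vals.mean(),
                "relative": vals.mean() / ctrl_mean,
                "t": t.statistic,
                "df": t.df,
                "p_raw": t.pvalue,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = (
        _holm(table["p_raw"].to_numpy()) if adjust == "holm" else table["p_raw"]
    )
    table["significant_raw"] = table["p_raw"] < alpha
    table["significant"] = table["p_adj"] < alpha
    table["direction"] = np.sign(table["mean"] - ctrl_mean)

    sig = table[table["significant"]]
    up = sig[sig["direction"] > 0]["level"].tolist()
    down = sig[sig["direction"] < 0]["level"].tolist()
    if up and down and any(u < d for u in up for d in down):
        cls = "biphasic"
    elif up and not down:
        cls = "monotonic_up"
    elif down and not up:
        cls = "monotonic_down"
    elif not up and not down:
        cls = "flat"
    else:  # mixed but not low-up/high-down: sign at highest significant dose
        cls = (
            "monotonic_up"
            if max(up) > max(down)
            else "monotonic_down"
        )

    rel = {0.0: 1.0}
    rel.update({row["level"]: row["relative"] for _, row in table.iterrows()})
    return DoseResponseProfile(
        levels=[0.0] + doses,
        relative_activity=rel,
        tests=table,
        classification=cls,
        alpha=alpha,
        adjust=adjust,
    )


# --- two-way ANOVA with Tukey HSD and compact letter display ---------------

def _maximal_cliques(nodes: list, adjacent) -> list:
    """Bron-Kerbosch without pivoting; fine for the <= handful of groups here."""
    cliques = []

    def bk(R: set, P: set, X: set) -> None:
        if not P and not X:
            cliques.append(R)
            return
        for vtx in list(P):
            bk(
                R | {vtx},
                {u for u in P if u != vtx and adjacent(u, vtx)},
                {u for u in X if u != vtx and adjacent(u, vtx)},
            )
            P.remove(vtx)
            X.add(vtx)

    bk(set(), set(nodes), set())
    return cliques


def compact_letter_display(groups: Sequence, sig_pairs: set) -> dict:
    """Assign letters so groups share a letter iff not significantly different.

    ``sig_pairs`` holds frozensets of group pairs that differ significantly.
    Letters come from the maximal cliques of the non-significance graph,
    ordered by first group appearance, which makes the display exactly
    consistent with the pairwise matrix.
    """
    groups = list(groups)
    index = {g: i for i, g in enumerate(groups)}

    def adjacent(u, v):
        return frozenset((u, v)) not in sig_pairs

    cliques = _maximal_cliques(groups, adjacent)
    cliques.sort(key=lambda c: min(index[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        for g in clique:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def anova2_tukey(
    table: pd.DataFrame,
    response: str = "rate",
    variant: str = "variant",
    level: str = "level",
    alpha: float = 0.05,
) -> TestResult:
    """Two-way ANOVA (type II) then per-level Tukey HSD across variants.

    The layout is variant x modulator-level with replicate responses.
    Empty cells are an error (named); >= 2 replicates per cell required.
    Within each modulator level, all variant pairs are compared by Tukey's
    HSD and summarized as a compact letter display — variants sharing a
    letter do not differ significantly at ``alpha``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[[response, variant, level]].copy()
    df.columns = ["y", "g1", "g2"]
    counts = df.groupby(["g1", "g2"], sort=True).size()
    variants = sorted(df["g1"].unique())
    levels_ = sorted(df["g2"].unique())
    empty = [
        (v, l) for v in variants for l in levels_ if (v, l) not in counts.index
    ]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"cells with a single replicate: {list(small.index)}"
        )

    model = smf.ols("y ~ C(g1) * C(g2)", data=df).fit()
    atab = sm.stats.anova_lm(model, typ=2)

    pairwise: dict = {}
    letters: dict = {}
    for lvl in levels_:
        sub = df[df["g2"] == lvl]
        if len(variants) < 2:
            pairwise[lvl] = pd.DataFrame()
            letters[lvl] = {variants[0]: "a"}
            continue
        tk = pairwise_tukeyhsd(sub["y"].to_numpy(), sub["g1"].to_numpy(), alpha=alpha)
        ptab = pd.DataFrame(
            data=tk.summary().data[1:], columns=tk.summary().data[0]
        )
        pairwise[lvl] = ptab
        sig = {
            frozenset((row["group1"], row["group2"]))
            for _, row in ptab.iterrows()
            if bool(row["reject"])
        }
        letters[lvl] = compact_letter_display(variants, sig)

    interaction_row = atab.index[atab.index.str.contains(":")][0]
    return TestResult(
        statistic=float(atab.loc[interaction_row, "F"]),
        df=(
            float(atab.loc[interaction_row, "df"]),
            float(atab.loc["Residual", "df"]),
        ),
        pvalue=float(atab.loc[interaction_row, "PR(>F)"]),
        anova_table=atab,
        pairwise=pairwise,
        letters=letters,
    )
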