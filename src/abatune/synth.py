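"""Seeded synthetic-data generators with recorded ground truth.

Each generator emulates the statistical structure one analysis stage
assumes and returns both the dataset and a machine-readable truth record,
so parameter-recovery tests can close the loop: generate at known
parameters, fit, compare.

Defaults mirror the bench designs of the study this package models:

* titrations in the tight-binding regime — 2 nM protein titrated with
  0-16 nM ligand, sub-nanomolar to low-nanomolar Kd, 3 replicates;
* Michaelis-Menten assays at Vmax 1.19 pmol/min/ug and KM 5.21 uM for the
  control, on a 1-200 uM substrate grid that brackets KM;
* biphasic activity-vs-dose profiles (+30% at 2 nM, -30% at >= 50 nM);
* background proteomes with planted gapped-motif instances.

Noise is additive Gaussian throughout, with the standard deviation given
as a fraction of the relevant signal scale (signal span for titrations,
Vmax for rates, the level mean for dose-response, i.e. a CV). Identical
spec + seed always reproduces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import NM, TitrationDataset, fraction_bound
from .kinetics import UM, KineticsDataset
from .motif import (
    DEFAULT_MOTIF_TEXT,
    MotifPattern,
    ProteinRecord,
    parse_motif,
)

__all__ = [
    "TitrationSpec",
    "MMSpec",
    "DoseResponseSpec",
    "ProteomeSpec",
    "gen_titration",
    "gen_mm",
    "gen_dose_response",
    "gen_proteome",
    "expected_background_matches",
    "make_spec",
]

# Printed study parameters used as generator defaults
KA_WILDTYPE = 19.27e8  # L/mol
KA_E657A = 4.63e8
KA_Y678A = 2.03e8
VMAX_CONTROL = 1.19  # pmol/min/ug
VMAX_2NM = 1.58
VMAX_50NM = 0.75
KM_CONTROL_M = 5.21e-6  # mol/L
KM_10NM_M = 2.18e-6

TITRATION_GRID_NM = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0)
SUBSTRATE_GRID_UM = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)


def _check_noise(sd: float) -> None:
    if sd < 0:
        raise ValueError(f"noise sd must be non-negative, got {sd}")


@dataclass
class TitrationSpec:
    """Design of a synthetic tight-binding titration."""

    seed: int
    kd: float = 1.0 / KA_WILDTYPE  # mol/L
    pt: float = 2.0 * NM
    ligand_nM: Sequence[float] = TITRATION_GRID_NM
    f0: float = 100.0
    df: float = 60.0  # signed; negative = quenching
    noise_frac: float = 0.01  # sd as a fraction of the model signal span
    replicates: int = 3
    ligand_name: str = "ABA"


def gen_titration(spec: TitrationSpec) -> tuple[TitrationDataset, dict]:
    """Simulate fluorescence titration points on the Morrison model.

    Noise sd is ``noise_frac`` times the model signal span
    ``|dF|*(max - min occupancy)``; zero noise lands exactly on the curve.
    """
    _check_noise(spec.noise_frac)
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.ligand_nM, dtype=float) * NM
    frac = fraction_bound(spec.pt, grid, spec.kd)
    span = abs(spec.df) * (frac.max() - frac.min())
    sd = spec.noise_frac * span

    La, F, rep = [], [], []
    for r in range(spec.replicates):
        mean = spec.f0 + spec.df * frac
        noisy = mean + rng.normal(0.0, sd, size=len(grid)) if sd > 0 else mean
        La.append(grid)
        F.append(noisy)
        rep.append(np.full(len(grid), r + 1))
    ds = TitrationDataset(
        protein_total=spec.pt,
        ligand_total=np.concatenate(La),
        fluorescence=np.concatenate(F),
        replicate=np.concatenate(rep),
        ligand_name=spec.ligand_name,
    )
    truth = {
        "kind": "titration",
        "kd_M": spec.kd,
        "ka_L_per_mol": 1.0 / spec.kd,
        "pt_M": spec.pt,
        "f0": spec.f0,
        "df": spec.df,
        "noise_sd": sd,
        "seed": spec.seed,
    }
    return ds, truth


@dataclass
class MMSpec:
    """Design of a synthetic Michaelis-Menten assay, possibly multi-level.

    ``levels`` maps modulator concentration (mol/L) to generating
    (Vmax, KM-in-mol/L) pairs; default is the control condition only.
    """

    seed: int
    levels: Mapping[float, tuple] = field(
        default_factory=lambda: {0.0: (VMAX_CONTROL, KM_CONTROL_M)}
    )
    substrate_uM: Sequence[float] = SUBSTRATE_GRID_UM
    noise_frac: float = 0.02  # sd as a fraction of each level's Vmax
    replicates: int = 3


def gen_mm(spec: MMSpec) -> tuple[KineticsDataset, dict]:
    """Simulate rate measurements v = Vmax*S/(KM+S) + N(0, noise_frac*Vmax)."""
    _check_noise(spec.noise_frac)
    rng = np.random.default_rng(spec.seed)
    S = np.asarray(spec.substrate_uM, dtype=float) * UM
    rows = []
    for mod in sorted(spec.levels):
        vmax, km = spec.levels[mod]
        sd = spec.noise_frac * vmax
        for r in range(spec.replicates):
            mean = vmax * S / (km + S)
            noisy = mean + rng.normal(0.0, sd, size=len(S)) if sd > 0 else mean
            for s_val, v_val in zip(S, noisy):
                rows.append(
                    {
                        "substrate_M": s_val,
                        "modulator_M": mod,
                        "replicate": r + 1,
                        "rate": v_val,
                    }
                )
    ds = KineticsDataset(pd.DataFrame(rows))
    truth = {
        "kind": "mm_kinetics",
        "levels": {
            f"{m:g}": {"vmax": vk[0], "km_M": vk[1]} for m, vk in spec.levels.items()
        },
        "noise_frac": spec.noise_frac,
        "seed": spec.seed,
    }
    return ds, truth


@dataclass
class DoseResponseSpec:
    """Replicate activity table: control plus multiplicative dose effects.

    ``effects`` maps modulator concentration (mol/L) to the fractional
    change in mean activity; the default profile is hormetic, matching a
    +30% stimulation at 2 nM fading to -30% inhibition at 50-100 nM.
    """

    seed: int
    control_mean: float = 1.19
    effects: Mapping[float, float] = field(
        default_factory=lambda: {
            2e-9: 0.30,
            10e-9: 0.15,
            50e-9: -0.30,
            100e-9: -0.30,
        }
    )
    cv: float = 0.05  # per-level coefficient of variation
    replicates: int = 3


def gen_dose_response(spec: DoseResponseSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate per-level replicate activities around multiplicative means."""
    _check_noise(spec.cv)
    rng = np.random.default_rng(spec.seed)
    rows = []
    levels = [0.0] + sorted(spec.effects)
    for lvl in levels:
        mean = spec.control_mean * (1.0 + (spec.effects.get(lvl, 0.0)))
        sd = spec.cv * mean
        vals = (
            mean + rng.normal(0.0, sd, size=spec.replicates)
            if sd > 0
            else np.full(spec.replicates, mean)
        )
        for r, v_val in enumerate(vals):
            rows.append({"modulator_M": lvl, "replicate": r + 1, "activity": v_val})
    df = pd.DataFrame(rows)

    # generating classification, from the signs of the designed effects
    ups = [m for m, e in spec.effects.items() if e > 0]
    downs = [m for m, e in spec.effects.items() if e < 0]
    if ups and downs and any(u < d for u in ups for d in downs):
        cls = "biphasic"
    elif ups and not downs:
        cls = "monotonic_up"
    elif downs and not ups:
        cls = "monotonic_down"
    else:
        cls = "flat"
    truth = {
        "kind": "dose_response",
        "control_mean": spec.control_mean,
        "effects": {f"{m:g}": e for m, e in spec.effects.items()},
        "cv": spec.cv,
        "classification": cls,
        "seed": spec.seed,
    }
    return df, truth


@dataclass
class ProteomeSpec:
    """Background proteome with planted gapped-motif instances."""

    seed: int
    n_sequences: int = 50
    n_planted: int = 10  # planted in the first n_planted sequences
    length_range: tuple = (300, 700)
    motif_text: str = DEFAULT_MOTIF_TEXT
    residue_freqs: Mapping[str, float] | None = None  # default uniform over 20

    def __post_init__(self) -> None:
        if not (0 <= self.n_planted <= self.n_sequences):
            raise ValueError("n_planted must be between 0 and n_sequences")


def _background(rng, length: int, letters: np.ndarray, probs: np.ndarray) -> list:
    return list(rng.choice(letters, size=length, p=probs))


def gen_proteome(spec: ProteomeSpec) -> tuple[list, pd.DataFrame]:
    """Generate random protein sequences, planting one motif instance in each
    of the first ``n_planted`` sequences at a random viable offset.

    Returns the records and a ground-truth table of planted anchor
    positions (1-based). Planted instances satisfy the pattern by
    construction; background may contain additional chance matches.
    """
    pattern = parse_motif(spec.motif_text)
    rng = np.random.default_rng(spec.seed)
    freqs = spec.residue_freqs or {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    letters = np.array(sorted(freqs))
    probs = np.array([freqs[l] for l in letters], dtype=float)
    probs = probs / probs.sum()

    records, truth_rows = [], []
    for i in range(spec.n_sequences):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        length = max(length, pattern.max_span())
        seq = _background(rng, length, letters, probs)
        pid = f"SYN{i + 1:04d}"
        if i < spec.n_planted:
            gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in pattern.gaps]
            span = pattern.n_anchors + sum(gaps)
            start = int(rng.integers(0, length - span + 1))  # 0-based
            pos = start
            anchor_positions = []
            for k, anchor in enumerate(pattern.anchors):
                seq[pos] = str(rng.choice(sorted(anchor)))
                anchor_positions.append(pos + 1)  # 1-based
                if k < len(gaps):
                    pos += gaps[k] + 1
            truth_rows.append(
                {
                    "protein_id": pid,
                    "anchor_positions": ",".join(map(str, anchor_positions)),
                    "start": anchor_positions[0],
                    "end": anchor_positions[-1],
                }
            )
        records.append(ProteinRecord(id=pid, sequence="".join(seq)))
    return records, pd.DataFrame(
        truth_rows, columns=["protein_id", "anchor_positions", "start", "end"]
    )


def expected_background_matches(
    pattern: MotifPattern,
    length: int,
    residue_freqs: Mapping[str, float] | None = None,
) -> float:
    """Expected number of motif placements in one i.i.d. background sequence.

    Sums, over every combination of gap lengths, the number of start
    offsets times the product of per-anchor match probabilities. Linearity
    of expectation makes this exact for i.i.d. residues.
    """
    freqs = residue_freqs or {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    total = sum(freqs.values())
    p_anchor = [sum(freqs.get(a, 0.0) for a in anchor) / total for anchor in pattern.anchors]
    p_tuple = float(np.prod(p_anchor))

    from itertools import product as iproduct

    expected = 0.0
    ranges = [range(lo, hi + 1) for lo, hi in pattern.gaps]
    for gaps in iproduct(*ranges):
        span = pattern.n_anchors + sum(gaps)
        expected += max(0, length - span + 1) * p_tuple
    return expected


def make_spec(kind: str, params: Mapping, seed: int):
    """Build a generator spec from a plain parameter mapping (CLI entry)."""
    classes = {
        "titration": TitrationSpec,
        "mm_kinetics": MMSpec,
        "dose_response": DoseResponseSpec,
        "proteome": ProteomeSpec,
    }
    if kind not in classes:
        raise ValueError(f"unknown kind {kind!r}; choose from {sorted(classes)}")
    params = dict(params)
    # JSON object keys arrive as strings; concentration-keyed maps need floats
    for key in ("levels", "effects"):
        if key in params and isinstance(params[key], Mapping):
            params[key] = {
                float(k): tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in params[key].items()
            }
    if "length_range" in params:
        params["length_range"] = tuple(params["length_range"])
    return classes[kind](seed=seed, **params)
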