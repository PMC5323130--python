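"""Steady-state SPR affinity analysis.

The steady-state response of a 1:1 interaction at analyte concentration C
follows the Langmuir isotherm RU(C) = Rmax·C/(KD + C); fitting it to a
titration series yields the equilibrium dissociation constant KD and the
saturation response Rmax.  Fitting is bounded nonlinear least squares
restarted from a grid of initial KD guesses spanning the concentration
range by decades, which makes the result insensitive to the starting point.

For competition experiments (receptor pre-incubated with an inhibitor and
flowed over an immobilized ligand), the expected relative signal follows
from mass-action equilibrium of the pre-incubation mix: the receptor–
inhibitor complex concentration is the root of a quadratic, and the SPR
signal is proportional to the occupancy of the immobilized ligand by the
remaining free receptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingIsotherm",
    "IllConditionedFit",
    "steady_state_response",
    "fit_steady_state",
    "make_isotherm",
    "simulate_competition",
    "read_isotherm",
    "write_isotherm",
]


class IllConditionedFit(UserWarning):
    pass


@dataclass
class BindingIsotherm:
    concentrations: np.ndarray  # μM, strictly increasing, ≥ 0
    responses: np.ndarray  # RU
    fitted_kd: float | None = None  # μM
    fitted_rmax: float | None = None  # RU
    fit_residual: float | None = None  # RU, root-mean-square
    kd_is_lower_bound: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration and response arrays differ in length")
        if len(self.concentrations) < 4:
            raise ValueError("need ≥ 4 titration points")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be ≥ 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


def steady_state_response(conc, kd: float, rmax: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (kd + conc)


def make_isotherm(kd: float, rmax: float, concs, noise_sd: float = 0.0,
                  seed: int = 0, noise_mode: str = "absolute") -> BindingIsotherm:
    """Synthetic titration series with seeded Gaussian noise; the generating
    truth is recorded in metadata for recovery tests.

    ``noise_mode="absolute"`` adds noise with a fixed RU standard deviation;
    ``"relative"`` scales the standard deviation by each point's noiseless
    response (signal-proportional error, the usual behaviour of an SPR
    trace), in which case ``noise_sd`` is the fractional level (0.05 = 5 %).
    """
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    if noise_mode not in ("absolute", "relative"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    concs = np.asarray(concs, dtype=float)
    resp = steady_state_response(concs, kd, rmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd * resp if noise_mode == "relative" else noise_sd
        resp = resp + rng.normal(0.0, 1.0, size=resp.shape) * sd
    return BindingIsotherm(concentrations=concs, responses=resp,
                           metadata={"true_kd": kd, "true_rmax": rmax,
                                     "noise_sd": noise_sd,
                                     "noise_mode": noise_mode, "seed": seed})


def fit_steady_state(iso: BindingIsotherm) -> BindingIsotherm:
    """Fit (KD, Rmax) by grid-restarted bounded least squares.

    Data without measurable curvature (responses ~linear in C, i.e. far
    below KD) are flagged: the returned KD is then only a lower bound."""
    conc = iso.concentrations
    resp = iso.responses
    pos = conc[conc > 0]
    if len(pos) < 2 or pos.max() / pos.min() < 10.0:
        raise ValueError("need a ≥ 10-fold concentration span for fitting")

    if np.allclose(resp, 0.0):
        warnings.warn("all responses are zero; fit is ill-conditioned",
                      IllConditionedFit)
        iso.fitted_kd, iso.fitted_rmax = None, None
        iso.kd_is_lower_bound = True
        return iso

    def residual(p):
        kd, rmax = p
        return steady_state_response(conc, kd, rmax) - resp

    lo = pos.min() / 1e3
    hi = pos.max() * 1e3
    kd_grid = 10.0 ** np.arange(np.floor(np.log10(lo)), np.ceil(np.log10(hi)) + 1)
    best = None
    rmax0 = max(resp.max(), 1e-6)
    for kd0 in kd_grid:
        try:
            fit = least_squares(residual, x0=[kd0, rmax0],
                                bounds=([lo / 10, 1e-9], [hi * 10, np.inf]))
        except ValueError:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    kd, rmax = best.x
    iso.fitted_kd = float(kd)
    iso.fitted_rmax = float(rmax)
    iso.fit_residual = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    # curvature check: a straight line through the origin explaining the data
    # as well as the isotherm means C ≪ KD throughout → KD unresolved
    slope = float((conc @ resp) / (conc @ conc))
    lin_rms = float(np.sqrt(np.mean((slope * conc - resp) ** 2)))
    scale = max(float(np.abs(resp).max()), 1e-12)
    if lin_rms <= max(iso.fit_residual, 1e-12 * scale) * (1 + 1e-6) or kd > pos.max() * 100:
        warnings.warn("no curvature in titration: KD is a lower bound only",
                      IllConditionedFit)
        iso.kd_is_lower_bound = True
    return iso


def simulate_competition(kd_ligand: float, kd_inhibitor: float,
                         receptor_total: float, inhibitor_concs) -> np.ndarray:
    """Expected relative SPR signal for a competitive pre-incubation assay.

    Free receptor after equilibration with inhibitor I (total concentrations,
    μM) follows from the quadratic mass-action solution; the reported signal
    is the immobilized-ligand occupancy by free receptor, normalized to the
    inhibitor-free signal (so the value at I = 0 is exactly 1).
    """
    if kd_ligand <= 0 or kd_inhibitor <= 0 or receptor_total <= 0:
        raise ValueError("all equilibrium parameters must be positive")
    I = np.asarray(inhibitor_concs, dtype=float)
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be ≥ 0")
    R, K = receptor_total, kd_inhibitor
    # complex RI from R_free·I_free/K = RI with conservation
    b = R + I + K
    ri = (b - np.sqrt(b * b - 4.0 * R * I)) / 2.0
    r_free = R - ri
    signal = r_free / (kd_ligand + r_free)
    return signal / (R / (kd_ligand + R))


# ---------------------------------------------------------------------------
# I/O: two-column delimited text (concentration μM, response RU)


def read_isotherm(path) -> BindingIsotherm:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (conc μM, response RU)")
    order = np.argsort(data[:, 0])
    return BindingIsotherm(concentrations=data[order, 0], responses=data[order, 1])


def write_isotherm(iso: BindingIsotherm, path) -> None:
    np.savetxt(path, np.column_stack([iso.concentrations, iso.responses]),
               fmt="%.6g", header="conc_uM\tresponse_RU", delimiter="\t")
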