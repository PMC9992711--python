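"""Mean-field kinetics of the M3 receptor-Gq activation/deactivation cycle.

The receptor is modelled as a closed first-order reaction network over
lumped conformational/complex states:

``R``
    unliganded receptor (the heterotrimeric G(GDP) pool is treated as
    non-depleting, so pre-assembly is not a separate species).
``RL``
    agonist-bound receptor, not yet G-coupled.
``RLG``
    agonist-bound receptor in complex with the intact heterotrimer.
``RLGx``
    as ``RLG`` but locked by a bound Gq inhibitor (YM-254890) that was not
    released on inhibitor washout; it can never exchange nucleotide.
``RLSep``
    agonist-bound receptor with Galpha-GTP and Gbetagamma separated but both
    still receptor-associated.
``RLSepPLC``
    ``RLSep`` with PLCbeta recruited to the Galpha-GTP arm.
``RGa`` / ``RGaPLC``
    post-washout receptor still holding Galpha-GTP (without Gbetagamma),
    without / with PLCbeta.

Forward activation is the irreversible chain RL -> RLG -> RLSep (rates
``k_couple`` and ``k_exch``); deactivation transitions (Gbetagamma release at
``k_bg_off``, GTP hydrolysis / Galpha release at ``k_hyd``, PLCbeta release
at ``k_plc_off``) are gated on agonist absence through a smooth occupancy
gate so that the receptor-G protein complex is stable while agonist is
present, as observed experimentally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError, ValidationError

__all__ = [
    "SPECIES",
    "RateSet",
    "ConditionSpec",
    "Transition",
    "ReactionNetwork",
    "StimulusProtocol",
    "StateTrajectory",
    "MacroscopicTargets",
    "build_network",
    "integrate",
    "closed_form_chain",
    "calibrate_rates",
]

#: Ordered state names of the reaction network.
SPECIES = ("R", "RL", "RLG", "RLGx", "RLSep", "RLSepPLC", "RGa", "RGaPLC")

AGONISTS = ("OxoM", "ACh")
NUCLEOTIDES = ("GTP", "GDPbetaS", "GTPgammaS")
GALPHA_VARIANTS = ("WT", "Q209L", "R183C")
RECEPTOR_VARIANTS = ("WT", "TripleA", "R166L")

#: Default multiplicative slowdown of nucleotide exchange under GDPbetaS
#: (the slow-step time constant is close to five-fold longer).
GDPBS_SLOWDOWN = 0.2

#: Default fraction of YM-locked complexes that resume cycling after the
#: inhibitor is washed out mid-protocol (~31% of step 2 reappears).
YM_UNBLOCKED_FRACTION = 0.31

#: Half-point (uM) of the smooth gate that keeps deactivation transitions
#: (Gbetagamma release, hydrolysis-driven Galpha release) shut while agonist
#: is present: small enough that leak at saturating agonist is negligible,
#: large enough that the gate opens within the ~20 ms solution exchange.
GATE_CONC = 1e-3


@dataclass(frozen=True)
class RateSet:
    """Microscopic first-order rate constants of the cycle (all 1/s except
    ``k_L_on`` in 1/(uM*s) and the dimensionless ``jitter_cv``)."""

    k_couple: float = 1.0 / 0.22
    k_exch: float = 1.0 / 1.92
    k_plc_on: float = 0.0
    k_bg_off: float = 1.0 / 0.47
    k_plc_off: float = 1.0 / 8.0
    k_hyd: float = 1.0 / 20.02
    k_L_on: float = math.log(2) / 0.05 / 0.112
    k_L_off: float = math.log(2) / 0.05
    jitter_cv: float = 0.2

    def __post_init__(self):
        for name in ("k_couple", "k_exch", "k_plc_on", "k_bg_off",
                     "k_plc_off", "k_hyd", "k_L_on", "k_L_off", "jitter_cv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"rate {name}={v!r} must be finite and >= 0")

    @property
    def ligand_kd(self) -> float:
        """Equilibrium dissociation constant of the agonist (uM)."""
        if self.k_L_on == 0:
            return math.inf
        return self.k_L_off / self.k_L_on

    def replace(self, **kw) -> "RateSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class ConditionSpec:
    """Experimental condition: agonist, nucleotide, drug schedule, variants."""

    agonist: str = "OxoM"
    concentration: float = 10.0
    nucleotide: str = "GTP"
    ym_schedule: tuple = ()
    galpha_variant: str = "WT"
    receptor_variant: str = "WT"
    grk2: bool = False
    construct: str = "hM3R-YFP-CFP"

    def __post_init__(self):
        if self.agonist not in AGONISTS:
            raise ConfigurationError(f"unknown agonist {self.agonist!r}")
        if self.nucleotide not in NUCLEOTIDES:
            raise ConfigurationError(f"unknown nucleotide {self.nucleotide!r}")
        if self.galpha_variant not in GALPHA_VARIANTS:
            raise ConfigurationError(f"unknown Galpha variant {self.galpha_variant!r}")
        if self.receptor_variant not in RECEPTOR_VARIANTS:
            raise ConfigurationError(f"unknown receptor variant {self.receptor_variant!r}")
        if self.concentration < 0:
            raise ValidationError("agonist concentration must be >= 0")
        ivs = sorted(tuple(map(float, iv)) for iv in self.ym_schedule)
        for (a0, a1) in ivs:
            if a1 <= a0:
                raise ValidationError(f"empty YM interval ({a0}, {a1})")
        for (_, a1), (b0, _) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValidationError("YM intervals overlap")
        object.__setattr__(self, "ym_schedule", tuple(ivs))

    @property
    def pre_separated(self) -> bool:
        """Constitutively active Galpha or GTPgammaS: the G pool rests with
        Galpha and Gbetagamma already apart, so there is no heterotrimer
        coupling step and no hydrolysis-limited slow OFF component."""
        return self.galpha_variant in ("Q209L", "R183C") or self.nucleotide == "GTPgammaS"

    @property
    def coupling_dead(self) -> bool:
        return self.receptor_variant in ("TripleA", "R166L")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant agonist/drug schedule with an exponential
    solution-exchange filter (bath exchange is complete within ~20 ms;
    default filter time constant 5 ms)."""

    duration: float
    dt: float = 0.1
    segments: tuple = ()   # (t_start, t_end, agonist_conc_uM, ym_present)
    exchange_tau: float = 0.005

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.exchange_tau < 0:
            raise ValidationError("exchange_tau must be >= 0")
        segs = tuple((float(a), float(b), float(c), bool(y))
                     for (a, b, c, y) in self.segments)
        if not segs:
            raise ValidationError("protocol needs at least one segment")
        if abs(segs[0][0]) > 1e-12 or abs(segs[-1][1] - self.duration) > 1e-9:
            raise ValidationError("segments must tile [0, duration]")
        for (_, a1, _, _), (b0, _, _, _) in zip(segs, segs[1:]):
            if abs(b0 - a1) > 1e-9:
                raise ValidationError("segments must tile [0, duration]")
        object.__setattr__(self, "segments", segs)

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt))
        return np.arange(n + 1) * self.dt

    @property
    def t_on(self) -> float:
        """Start of the first agonist-containing segment."""
        for (a, _, c, _) in self.segments:
            if c > 0:
                return a
        return math.nan

    @property
    def t_off(self) -> float:
        """End of the last agonist-containing segment."""
        out = math.nan
        for (_, b, c, _) in self.segments:
            if c > 0:
                out = b
        return out

    @property
    def _boundary_conc(self) -> tuple:
        """Filtered concentration at each segment start."""
        cached = self.__dict__.get("_bc")
        if cached is None:
            vals = [0.0]
            c = 0.0
            for (a, b, target, _) in self.segments:
                if self.exchange_tau == 0:
                    c = target
                else:
                    c = target + (c - target) * math.exp(
                        -(b - a) / self.exchange_tau)
                vals.append(c)
            cached = tuple(vals)
            object.__setattr__(self, "_bc", cached)
        return cached

    def concentration(self, t: float) -> float:
        """Exchange-filtered agonist concentration at time t (uM)."""
        bc = self._boundary_conc
        for i, (a, b, target, _) in enumerate(self.segments):
            last = i == len(self.segments) - 1
            if t <= b + 1e-12 or last:
                if t < a:
                    return bc[i]
                if self.exchange_tau == 0:
                    return target
                return target + (bc[i] - target) * math.exp(
                    -(t - a) / self.exchange_tau)
        return bc[-1]

    def ym_active(self, t: float) -> bool:
        for (a, b, _, y) in self.segments:
            if a <= t < b:
                return y
        return bool(self.segments[-1][3]) if t >= self.segments[-1][1] else False

    def ym_washout_times(self) -> list:
        """Times at which a YM-containing segment ends and YM goes away."""
        out = []
        for (seg, nxt) in zip(self.segments, self.segments[1:]):
            if seg[3] and not nxt[3]:
                out.append(seg[1])
        return out


def standard_protocol(baseline_s: float = 10.0, agonist_s: float = 15.0,
                      washout_s: float = 20.0, conc: float = 10.0,
                      hz: float = 10.0, ym_windows: Sequence = (),
                      exchange_tau: float = 0.005) -> StimulusProtocol:
    """Baseline -> agonist pulse -> washout, with optional YM intervals.

    YM windows are given in absolute protocol time and may span the
    baseline/agonist boundary; segments are split accordingly.
    """
    duration = baseline_s + agonist_s + washout_s
    edges = {0.0, baseline_s, baseline_s + agonist_s, duration}
    for (a, b) in ym_windows:
        if not (0 <= a < b <= duration):
            raise ValidationError("YM window outside protocol duration")
        edges.update((float(a), float(b)))
    cuts = sorted(edges)
    segs = []
    for a, b in zip(cuts, cuts[1:]):
        mid = 0.5 * (a + b)
        conc_here = conc if baseline_s <= mid < baseline_s + agonist_s else 0.0
        ym_here = any(w0 <= mid < w1 for (w0, w1) in ym_windows)
        segs.append((a, b, conc_here, ym_here))
    return StimulusProtocol(duration=duration, dt=1.0 / hz, segments=tuple(segs),
                            exchange_tau=exchange_tau)


@dataclass(frozen=True)
class Transition:
    """One first-order flow. ``kind`` selects the stimulus modifier:

    - ``const``: rate constant as given
    - ``ligand_on``: rate * C(t)        (agonist association)
    - ``exch``: rate, but 0 while YM is present
    - ``washout``: rate * (1 - C/(C + c_gate))  (runs after agonist removal)
    """

    source: str
    target: str
    rate: float
    kind: str = "const"

    def __post_init__(self):
        if self.source not in SPECIES or self.target not in SPECIES:
            raise ConfigurationError(f"unknown species in {self.source}->{self.target}")
        if not math.isfinite(self.rate) or self.rate < 0:
            raise ValidationError(
                f"transition {self.source}->{self.target} rate {self.rate!r} invalid")


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple
    transitions: tuple
    condition: ConditionSpec
    rates: RateSet
    gate_conc: float           # half-point (uM) of the washout gate
    ym_unblocked_fraction: float = YM_UNBLOCKED_FRACTION

    def index(self, name: str) -> int:
        return self.species.index(name)

    def rate_value(self, tr: Transition, conc: float, ym: bool) -> float:
        if tr.kind == "const":
            return tr.rate
        if tr.kind == "ligand_on":
            return tr.rate * conc
        if tr.kind == "exch":
            return 0.0 if ym else tr.rate
        if tr.kind == "washout":
            return tr.rate * (1.0 - conc / (conc + self.gate_conc))
        raise ConfigurationError(f"unknown transition kind {tr.kind!r}")


def build_network(condition: ConditionSpec, rates: RateSet,
                  gdpbs_slowdown: float = GDPBS_SLOWDOWN,
                  ym_unblocked_fraction: float = YM_UNBLOCKED_FRACTION,
                  ) -> ReactionNetwork:
    """Assemble the cycle with condition modifiers applied.

    GDPbetaS multiplies ``k_exch`` by ``gdpbs_slowdown``; YM intervals force
    the exchange transition to zero while present; constitutively active
    Galpha (Q209L/R183C) and GTPgammaS make the resting G pool pre-separated
    (direct RL -> RLSep engagement at ``k_couple``, no hydrolysis-limited
    OFF); coupling-dead receptors (3A, R166L) remove every G-bound path.
    """
    if not 0 <= ym_unblocked_fraction <= 1:
        raise ValidationError("ym_unblocked_fraction must lie in [0, 1]")
    k_exch = rates.k_exch
    if condition.nucleotide == "GDPbetaS":
        if not 0 <= gdpbs_slowdown:
            raise ValidationError("gdpbs_slowdown must be >= 0")
        k_exch = rates.k_exch * gdpbs_slowdown

    trs = [
        Transition("R", "RL", rates.k_L_on, "ligand_on"),
        Transition("RL", "R", rates.k_L_off, "const"),
    ]
    if not condition.coupling_dead:
        if condition.pre_separated:
            # Galpha-GTP and Gbetagamma engage the liganded receptor directly;
            # everything releases in the fast OFF step (no hydrolysis needed).
            trs += [
                Transition("RL", "RLSep", rates.k_couple, "const"),
                Transition("RLSep", "R", rates.k_bg_off, "washout"),
            ]
            if rates.k_plc_on > 0:
                trs += [
                    Transition("RLSep", "RLSepPLC", rates.k_plc_on, "const"),
                    Transition("RLSepPLC", "RLSep", rates.k_plc_off, "washout"),
                ]
        else:
            trs += [
                Transition("RL", "RLG", rates.k_couple, "const"),
                Transition("RLG", "RLSep", k_exch, "exch"),
                Transition("RLG", "R", rates.k_bg_off, "washout"),
                Transition("RLGx", "R", rates.k_bg_off, "washout"),
                Transition("RLSep", "RGa", rates.k_bg_off, "washout"),
                Transition("RGa", "R", rates.k_hyd, "const"),
            ]
            if rates.k_plc_on > 0:
                trs += [
                    Transition("RLSep", "RLSepPLC", rates.k_plc_on, "const"),
                    Transition("RLSepPLC", "RGaPLC", rates.k_bg_off, "washout"),
                    Transition("RGaPLC", "RGa", rates.k_plc_off, "const"),
                ]
    return ReactionNetwork(species=SPECIES, transitions=tuple(trs),
                           condition=condition, rates=rates,
                           gate_conc=GATE_CONC,
                           ym_unblocked_fraction=ym_unblocked_fraction)


@dataclass(frozen=True)
class StateTrajectory:
    """Occupancy fractions of every network species on the protocol grid."""

    t: np.ndarray
    species: tuple
    occupancy: np.ndarray  # shape (n_species, n_t)

    def fraction(self, name: str) -> np.ndarray:
        return self.occupancy[self.species.index(name)]

    def check(self, tol: float = 1e-8) -> None:
        total = self.occupancy.sum(axis=0)
        if np.any(np.abs(total - 1.0) > tol):
            raise ValidationError("occupancy not conserved")
        if np.any(self.occupancy < -tol) or np.any(self.occupancy > 1 + tol):
            raise ValidationError("occupancy outside [0, 1]")


def _rhs_factory(network: ReactionNetwork, protocol: StimulusProtocol
                 ) -> Callable[[float, np.ndarray], np.ndarray]:
    idx = {s: i for i, s in enumerate(network.species)}
    pairs = [(idx[tr.source], idx[tr.target], tr) for tr in network.transitions]

    def rhs(t, y):
        conc = protocol.concentration(t)
        ym = protocol.ym_active(t)
        dy = np.zeros_like(y)
        for i, j, tr in pairs:
            flow = network.rate_value(tr, conc, ym) * y[i]
            dy[i] -= flow
            dy[j] += flow
        return dy

    return rhs


def integrate(network: ReactionNetwork, protocol: StimulusProtocol,
              y0: np.ndarray | None = None, rtol: float = 1e-7,
              atol: float = 1e-9) -> StateTrajectory:
    """Integrate the mean-field ODE of the network over the protocol.

    The stimulus is handled piecewise: integration restarts at every segment
    boundary (the exchange filter makes the forcing continuous but not
    smooth there).  When a YM-containing segment ends, a fraction
    ``1 - ym_unblocked_fraction`` of the YM-bound heterotrimer complexes is
    moved into the permanently locked ``RLGx`` state.
    """
    t_grid = protocol.grid
    if y0 is None:
        y = np.zeros(len(network.species))
        y[network.index("R")] = 1.0
    else:
        y = np.asarray(y0, dtype=float).copy()
        if y.shape != (len(network.species),):
            raise ValidationError("y0 has wrong shape")
    rhs = _rhs_factory(network, protocol)
    washouts = set(protocol.ym_washout_times())
    edges = sorted({round(s[0], 12) for s in protocol.segments}
                   | {protocol.duration})
    out = np.empty((len(network.species), len(t_grid)))
    out[:, 0] = y
    pos = 1
    for a, b in zip(edges, edges[1:]):
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12)
        t_eval = t_grid[mask]
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, max_step=max(b - a, 1e-3))
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a}, {b}]: {sol.message}",
                segment=(a, b))
        if t_eval.size:
            out[:, pos:pos + t_eval.size] = sol.y
            pos += t_eval.size
        y = sol.y[:, -1] if sol.y.size else y
        if any(abs(b - w) < 1e-9 for w in washouts):
            i_rlg, i_rlgx = network.index("RLG"), network.index("RLGx")
            locked = (1.0 - network.ym_unblocked_fraction) * y[i_rlg]
            y = y.copy()
            y[i_rlg] -= locked
            y[i_rlgx] += locked
            out[:, pos - 1] = y  # boundary sample reflects the partition
    occ = np.clip(out, 0.0, None)
    total = occ.sum(axis=0)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise IntegrationError("mass conservation lost beyond solver tolerance")
    occ /= total  # renormalise away solver round-off
    traj = StateTrajectory(t=t_grid, species=network.species, occupancy=occ)
    traj.check(tol=1e-8)
    return traj


def closed_form_chain(k1: float, k2: float, t) -> tuple:
    """Occupancies of the irreversible chain A -> B -> C with A(0) = 1.

    Textbook sequential first-order decay; the repeated-root limit k1 == k2
    is handled continuously (B = k t exp(-k t)).
    """
    if not (math.isfinite(k1) and math.isfinite(k2)) or k1 <= 0 or k2 <= 0:
        raise ValidationError("chain rates must be finite and > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValidationError("times must be finite and >= 0")
    a = np.exp(-k1 * t)
    if abs(k1 - k2) <= 1e-10 * max(k1, k2):
        k = 0.5 * (k1 + k2)
        b = k * t * np.exp(-k * t)
    else:
        b = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    c = 1.0 - a - b
    return a, b, c


@dataclass(frozen=True)
class MacroscopicTargets:
    """Printed macroscopic time constants a preset is calibrated against."""

    tau1_on: float = 0.22
    tau2_on: float = 1.92
    tau1_off: float = 0.47
    tau2_off: float = 20.02
    delay_on: float = 0.08
    step1_fraction: float = 0.5

    def __post_init__(self):
        for name in ("tau1_on", "tau2_on", "tau1_off", "tau2_off", "delay_on"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.step1_fraction < 1:
            raise ValidationError("step1_fraction must lie in (0, 1)")


def calibrate_rates(targets: MacroscopicTargets, mode: str = "reciprocal",
                    base: RateSet | None = None, tol: float = 0.05,
                    ) -> RateSet:
    """Map macroscopic time constants to microscopic rates.

    ``reciprocal`` sets each lumped rate to the inverse of its target tau.
    ``refined`` then nudges (k_couple, k_exch) so that the full noiseless
    render -> analyze pipeline recovers the ON targets within ``tol``
    (relative); it raises :class:`CalibrationError` with the residuals if the
    self-consistency loop cannot reach the tolerance.
    """
    base = base or RateSet()
    rates = base.replace(k_couple=1.0 / targets.tau1_on,
                         k_exch=1.0 / targets.tau2_on,
                         k_bg_off=1.0 / targets.tau1_off,
                         k_hyd=1.0 / targets.tau2_off)
    if mode == "reciprocal":
        return rates
    if mode != "refined":
        raise ConfigurationError(f"unknown calibration mode {mode!r}")

    from .errors import CalibrationError
    from scipy.optimize import least_squares

    def residuals(logk):
        r = rates.replace(k_couple=float(np.exp(logk[0])),
                          k_exch=float(np.exp(logk[1])))
        t1, t2 = _noiseless_recovered_taus(r)
        return [math.log(t1 / targets.tau1_on), math.log(t2 / targets.tau2_on)]

    x0 = np.log([rates.k_couple, rates.k_exch])
    sol = least_squares(residuals, x0, diff_step=0.05, xtol=1e-4, ftol=1e-6)
    res = residuals(sol.x)
    if max(abs(r) for r in res) > math.log1p(tol):
        raise CalibrationError("refined calibration outside tolerance",
                               residuals=res)
    return rates.replace(k_couple=float(np.exp(sol.x[0])),
                         k_exch=float(np.exp(sol.x[1])))


def _noiseless_recovered_taus(rates: RateSet) -> tuple:
    """Recovered (tau1_on, tau2_on) of one noiseless wild-type cell run
    through the full pipeline (lazy imports avoid a module cycle)."""
    from .photometry import OpticsSpec, render_channels, true_fretr
    from .presets import get_preset
    from .analysis import compute_fretr, normalize_trace, fit_two_step

    preset = get_preset("wt_gtp")
    protocol = preset.make_protocol()
    net = build_network(preset.condition, rates)
    traj = integrate(net, protocol)
    ratio = true_fretr(traj, preset.pair)
    optics = OpticsSpec(noise_sd_donor=0.0, noise_sd_acceptor=0.0)
    ch = render_channels(traj.t, ratio, optics,
                         t_on=protocol.t_on, t_off=protocol.t_off)
    norm = normalize_trace(compute_fretr(ch), preset.pair.direction)
    fit = fit_two_step(norm, "ON")
    return fit.tau1, fit.tau2
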