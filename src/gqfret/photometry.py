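"""Synthetic two-channel FRET photometry.

A state trajectory is mapped to a construct-specific true FRET ratio
(pointwise weighted sum of per-state coefficients) and rendered into donor
(CFPc) and acceptor (YFPc) channel intensities with donor bleed-through,
shared photobleaching, and i.i.d. Gaussian channel noise.  The render is the
exact inverse of the ratio computation in the noiseless limit::

    CFPc(t) = D * exp(-b*t)
    YFPc(t) = (ratio(t) + cFactor) * D * exp(-b*t)
    =>  (YFPc - cFactor*CFPc) / CFPc == ratio

Per-cell biological variability is emulated by lognormal jitter on the
kinetic rates (CV ``RateSet.jitter_cv``) and on the response amplitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .kinetics import (RateSet, SPECIES, StateTrajectory, StimulusProtocol,
                       build_network, integrate)

__all__ = [
    "FretPairSpec",
    "OpticsSpec",
    "ChannelTraces",
    "Cell",
    "CellDataset",
    "true_fretr",
    "render_channels",
    "noise_sd_for_snr",
    "jitter_rates",
    "generate_cells",
    "generate_dose_series",
    "write_dataset",
    "read_traces",
]

#: Per-cell lognormal CV applied to the response amplitude.
AMPLITUDE_JITTER_CV = 0.10


@dataclass(frozen=True)
class FretPairSpec:
    """Per-state true-FRET-ratio coefficients of one donor/acceptor pair."""

    name: str
    epsilon: dict
    direction: str  # "decrease" | "increase" upon activation

    def __post_init__(self):
        missing = [s for s in SPECIES if s not in self.epsilon]
        if missing:
            raise ConfigurationError(
                f"pair {self.name!r} lacks coefficients for {missing}")
        if any(not math.isfinite(v) for v in self.epsilon.values()):
            raise ValidationError(f"pair {self.name!r} has non-finite coefficients")
        if self.direction not in ("decrease", "increase"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        base = self.epsilon["R"]
        lo, hi = min(self.epsilon.values()), max(self.epsilon.values())
        if self.direction == "decrease" and not lo < base:
            raise ValidationError(f"pair {self.name!r}: no state below baseline")
        if self.direction == "increase" and not hi > base:
            raise ValidationError(f"pair {self.name!r}: no state above baseline")

    @property
    def baseline_fretr(self) -> float:
        return self.epsilon["R"]

    @property
    def full_amplitude(self) -> float:
        """Largest deviation of any state coefficient from baseline."""
        return max(abs(v - self.baseline_fretr) for v in self.epsilon.values())

    def scaled(self, factor: float) -> "FretPairSpec":
        """Scale all deviations from baseline by ``factor``."""
        base = self.baseline_fretr
        eps = {s: base + factor * (v - base) for s, v in self.epsilon.items()}
        return FretPairSpec(name=self.name, epsilon=eps, direction=self.direction)


@dataclass(frozen=True)
class OpticsSpec:
    """Detection model: bleed-through, donor brightness, noise, bleaching."""

    cFactor: float = 0.45
    donor_base: float = 100.0
    noise_sd_donor: float = 0.0
    noise_sd_acceptor: float = 0.0
    bleach_rate: float = 0.0
    #: extra acceptor-channel bleach that does NOT cancel in the ratio;
    #: defaults off (shared bleaching cancels exactly).
    acceptor_extra_bleach: float = 0.0

    def __post_init__(self):
        if self.cFactor < 0:
            raise ValidationError("cFactor must be >= 0")
        if self.donor_base <= 0:
            raise ValidationError("donor_base must be > 0")
        if self.noise_sd_donor < 0 or self.noise_sd_acceptor < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.bleach_rate < 0 or self.acceptor_extra_bleach < 0:
            raise ValidationError("bleach rates must be >= 0")


@dataclass(frozen=True)
class ChannelTraces:
    """Sampled donor/acceptor intensities plus the stimulus marks."""

    t: np.ndarray
    cfp_c: np.ndarray
    yfp_c: np.ndarray
    t_on: float = math.nan
    t_off: float = math.nan

    def __post_init__(self):
        if not (len(self.t) == len(self.cfp_c) == len(self.yfp_c)):
            raise ValidationError("channel arrays must share the time grid")


def true_fretr(traj: StateTrajectory, pair: FretPairSpec) -> np.ndarray:
    """Noise-free FRET ratio: sum_s epsilon_s * occupancy_s(t)."""
    out = np.zeros_like(traj.t, dtype=float)
    for s in traj.species:
        out += pair.epsilon[s] * traj.fraction(s)
    return out


def render_channels(t: np.ndarray, ratio: np.ndarray, optics: OpticsSpec,
                    rng: np.random.Generator | None = None,
                    t_on: float = math.nan, t_off: float = math.nan,
                    ) -> ChannelTraces:
    """Render a true ratio into two-channel photometry samples."""
    ratio = np.asarray(ratio, dtype=float)
    if not np.all(np.isfinite(ratio)):
        raise ValidationError("ratio trace must be finite")
    base = optics.donor_base * np.exp(-optics.bleach_rate * np.asarray(t))
    cfp = base.copy()
    yfp = (ratio + optics.cFactor) * base * np.exp(
        -optics.acceptor_extra_bleach * np.asarray(t))
    if rng is not None and (optics.noise_sd_donor or optics.noise_sd_acceptor):
        cfp = cfp + rng.normal(0.0, optics.noise_sd_donor, size=cfp.shape)
        yfp = yfp + rng.normal(0.0, optics.noise_sd_acceptor, size=yfp.shape)
    return ChannelTraces(t=np.asarray(t), cfp_c=cfp, yfp_c=yfp,
                         t_on=t_on, t_off=t_off)


def noise_sd_for_snr(pair: FretPairSpec, target_snr: float,
                     optics: OpticsSpec, hz: float,
                     baseline_s: float = 5.0) -> float:
    """Per-channel noise SD giving the requested pipeline SNR.

    SNR is the maximum response amplitude over the standard error of the
    baseline (SD / sqrt(n) over a ``baseline_s`` window at ``hz``).  First-
    order error propagation of the two channel noises through the ratio
    gives  var(r) ~ (sd_a^2 + (r0 + cFactor)^2 sd_d^2) / D^2; with equal
    per-channel SDs this is solved for the SD.
    """
    if target_snr <= 0:
        raise ValidationError("target SNR must be > 0")
    n = int(round(baseline_s * hz))
    sigma_r = pair.full_amplitude * math.sqrt(n) / target_snr
    r0 = pair.baseline_fretr
    return sigma_r * optics.donor_base / math.sqrt(
        1.0 + (r0 + optics.cFactor) ** 2)


def jitter_rates(rates: RateSet, rng: np.random.Generator,
                 cv: float | None = None) -> RateSet:
    """Lognormal per-cell jitter (mean 1) on every kinetic rate constant."""
    cv = rates.jitter_cv if cv is None else cv
    if cv == 0:
        return rates
    sigma = math.sqrt(math.log1p(cv * cv))
    kw = {}
    for name in ("k_couple", "k_exch", "k_bg_off", "k_hyd",
                 "k_plc_on", "k_plc_off"):
        f = float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
        kw[name] = getattr(rates, name) * f
    return rates.replace(**kw)


@dataclass(frozen=True)
class Cell:
    cell_id: str
    traces: ChannelTraces
    true_rates: RateSet
    amp_scale: float = 1.0


@dataclass
class CellDataset:
    """A reproducible batch of simulated cells for one condition preset."""

    preset_name: str
    seed: int
    hz: float
    protocol: StimulusProtocol
    pair: FretPairSpec
    cells: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cell in self.cells:
            frames.append(pd.DataFrame({
                "cell_id": cell.cell_id,
                "time_s": cell.traces.t,
                "cfp_c": cell.traces.cfp_c,
                "yfp_c": cell.traces.yfp_c,
            }))
        return pd.concat(frames, ignore_index=True)

    def sidecar(self) -> dict:
        return {
            "preset": self.preset_name,
            "seed": int(self.seed),
            "hz": self.hz,
            "t_on": self.protocol.t_on,
            "t_off": self.protocol.t_off,
            "direction": self.pair.direction,
            "cells": {
                c.cell_id: {
                    "amp_scale": c.amp_scale,
                    "rates": {k: getattr(c.true_rates, k)
                              for k in ("k_couple", "k_exch", "k_plc_on",
                                        "k_bg_off", "k_plc_off", "k_hyd",
                                        "k_L_on", "k_L_off")},
                } for c in self.cells
            },
        }


def generate_cells(preset_name: str, n: int, seed: int, hz: float | None = None,
                   noise_scale: float = 1.0, jitter_cv: float | None = None,
                   ) -> CellDataset:
    """Simulate ``n`` cells of a named condition preset.

    Deterministic given (preset, n, seed): cell seeds are spawned from a
    single :class:`numpy.random.SeedSequence`.
    """
    from .presets import get_preset

    if n < 1:
        raise ValidationError("n must be >= 1")
    preset = get_preset(preset_name)
    hz = hz if hz is not None else preset.hz
    protocol = preset.make_protocol(hz=hz)
    optics = preset.optics
    sd = noise_sd_for_snr(preset.pair, preset.snr_target, optics, hz) \
        * noise_scale if preset.snr_target else 0.0
    optics = OpticsSpec(cFactor=optics.cFactor, donor_base=optics.donor_base,
                        noise_sd_donor=sd, noise_sd_acceptor=sd,
                        bleach_rate=optics.bleach_rate,
                        acceptor_extra_bleach=optics.acceptor_extra_bleach)
    ds = CellDataset(preset_name=preset_name, seed=seed, hz=hz,
                     protocol=protocol, pair=preset.pair)
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(ss)
        rates_i = jitter_rates(preset.rates, rng, cv=jitter_cv)
        net = build_network(preset.condition, rates_i,
                            ym_unblocked_fraction=preset.ym_unblocked_fraction)
        traj = integrate(net, protocol)
        amp = 1.0 if (jitter_cv == 0) else float(
            rng.lognormal(-0.5 * math.log1p(AMPLITUDE_JITTER_CV ** 2),
                          math.sqrt(math.log1p(AMPLITUDE_JITTER_CV ** 2))))
        ratio = true_fretr(traj, preset.pair.scaled(amp))
        traces = render_channels(traj.t, ratio, optics, rng=rng,
                                 t_on=protocol.t_on, t_off=protocol.t_off)
        ds.cells.append(Cell(cell_id=f"{preset_name}_{i:03d}", traces=traces,
                             true_rates=rates_i, amp_scale=amp))
    return ds


def generate_dose_series(preset_name: str, concentrations, n_per_conc: int,
                         seed: int) -> pd.DataFrame:
    """Peak responses across an agonist concentration series.

    The preset is simulated at its (saturating) reference concentration and
    the response amplitude is scaled by the equilibrium receptor occupancy
    c / (c + Kd) at each tested concentration -- a fast-equilibrium
    amplitude model with Kd taken from the preset's agonist affinity.
    Returns a tidy frame (conc_uM, cell_id, peak_dfretr).
    """
    from .presets import get_preset
    from .analysis import compute_fretr

    preset = get_preset(preset_name)
    protocol = preset.make_protocol()
    kd = preset.rates.ligand_kd
    optics = preset.optics
    sd = noise_sd_for_snr(preset.pair, preset.snr_target, optics, preset.hz) \
        if preset.snr_target else 0.0
    optics = OpticsSpec(cFactor=optics.cFactor, donor_base=optics.donor_base,
                        noise_sd_donor=sd, noise_sd_acceptor=sd)
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(list(concentrations)))
    for conc, ss in zip(concentrations, seeds):
        occ = conc / (conc + kd)
        for i, cell_ss in enumerate(ss.spawn(n_per_conc)):
            rng = np.random.default_rng(cell_ss)
            rates_i = jitter_rates(preset.rates, rng)
            net = build_network(preset.condition, rates_i)
            traj = integrate(net, protocol)
            ratio = true_fretr(traj, preset.pair.scaled(occ))
            ch = render_channels(traj.t, ratio, optics, rng=rng,
                                 t_on=protocol.t_on, t_off=protocol.t_off)
            fr = compute_fretr(ch, cfactor=optics.cFactor)
            base = fr.fretr[fr.t < fr.t_on][-int(5 * preset.hz):].mean()
            resp = fr.fretr[(fr.t >= fr.t_on) & (fr.t <= fr.t_off)]
            rows.append({"conc_uM": conc, "cell_id": f"c{conc:g}_{i:03d}",
                         "peak_dfretr": float(np.max(np.abs(resp - base)))})
    return pd.DataFrame(rows)


def write_dataset(ds: CellDataset, out_dir) -> tuple:
    """Write long-format traces CSV plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{ds.preset_name}_traces.csv"
    json_path = out / f"{ds.preset_name}_truth.json"
    ds.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
    json_path.write_text(json.dumps(ds.sidecar(), indent=1, sort_keys=True))
    return csv_path, json_path


def read_traces(csv_path, t_on: float = math.nan, t_off: float = math.nan,
                ) -> dict:
    """Read a long-format traces CSV back into per-cell ChannelTraces."""
    df = pd.read_csv(csv_path)
    need = {"cell_id", "time_s", "cfp_c", "yfp_c"}
    if not need.issubset(df.columns):
        raise ValidationError(f"trace CSV must have columns {sorted(need)}")
    out = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        out[str(cid)] = ChannelTraces(
            t=grp["time_s"].to_numpy(), cfp_c=grp["cfp_c"].to_numpy(),
            yfp_c=grp["yfp_c"].to_numpy(), t_on=t_on, t_off=t_off)
    return out
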