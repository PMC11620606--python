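"""Forward amelogenesis simulator with exact ground-truth chronology.

The model grows a 2-D longitudinal section of a (deciduous first molar)
mesio-buccal cusp:

* the EDJ is a circular arc from dentine horn to cervix; ameloblast
  recruitment along it follows an enamel-extension-rate schedule
  EER(t) = floor + (initial - floor) * exp(-t / tau), integrated into a
  recruitment front A(t); crown formation ends when the front reaches
  the cervix, so the chained-segment identity sum(days) = CFT holds by
  construction;
* each recruited ameloblast secretes radially outward; the daily
  secretion rate is constant within the inner 200 µm (a smooth seeded
  field along the EDJ times a prenatal/postnatal step at birth) and
  ramps up linearly beyond it, emulating the low-inner / high-outer
  topography of real enamel;
* striae of Retzius are isochrones of the growth field, emitted
  periodically and at every chain-segment boundary; the neonatal line
  is the isochrone of the birth day and accentuated lines those of the
  stress days;
* cross-striation runs sample the local true DSR at evenly spaced
  depths within each chained segment, with multiplicative measurement
  noise ~ Normal(1, noise_cv).

Everything the analysis pipeline later estimates (CFT, Ci, Cc, AL ages,
EER profile, DSR field) is recorded exactly in :class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .geometry import Point2D, Polyline
from .tracings import (
    CrossStriationRun,
    PrismSegmentTrace,
    SectionFlags,
    StriaTrace,
    ToothSection,
)

SEGMENT_UM = 200.0          # nominal chained prism segment length
INNER_ZONE_UM = 200.0       # depth of the constant-DSR inner enamel

__all__ = [
    "EERSchedule",
    "GrowthParams",
    "GroundTruth",
    "CohortJitter",
    "default_params",
    "simulate_tooth",
    "make_cohort",
    "sample_dsr_field",
]


@dataclass(frozen=True)
class EERSchedule:
    """Exponentially decaying ameloblast recruitment speed (µm/day).

    Rapid cuspal recruitment decaying with time constant ``tau`` to a
    slow cervical ``floor`` — the canonical crown-growth shape.
    """

    initial: float = 12.0
    floor: float = 3.5
    tau: float = 120.0

    def rate(self, t):
        return self.floor + (self.initial - self.floor) * np.exp(-np.asarray(t) / self.tau)

    def front(self, t):
        """Cumulative EDJ arc recruited by time t (µm)."""
        t = np.asarray(t)
        return self.floor * t + (self.initial - self.floor) * self.tau * (
            1.0 - np.exp(-t / self.tau)
        )

    def time_at_arc(self, arc: float, t_max: float = 1e5) -> float:
        """Inverse of :meth:`front`."""
        return float(brentq(lambda t: float(self.front(t)) - arc, 0.0, t_max))


@dataclass(frozen=True)
class GrowthParams:
    """Ground-truth growth parameters of one simulated tooth."""

    cft_true: float = 386.0          # days, crown initiation -> completion
    ci_true: float = 172.0           # days before birth at initiation
    edj_length: float = 0.0          # µm; 0 = derive from the EER schedule
    edj_radius: float = 2500.0       # µm, circular-arc EDJ shape parameter
    eer_schedule: EERSchedule = field(default_factory=EERSchedule)
    dsr_inner_mean: float = 3.17     # µm/day, inner-enamel population mean
    dsr_inner_rel_sd: float = 0.075  # relative sd of the along-EDJ DSR field
    dsr_outer_gain: float = 0.8      # relative DSR rise per 1000 µm beyond the inner zone
    postnatal_dsr_shift: float = -0.025   # postnatal/prenatal rate ratio - 1
    secretion_span: float = 250.0    # days each ameloblast keeps secreting
    retzius_period: float = 8.0      # days between background striae (assumed)
    al_days: tuple = (-40.0, 120.0)  # accentuated-line days relative to birth
    runs_per_segment: int = 8        # cross-striation runs measured per segment
    noise_cv: float = 0.03           # multiplicative run-length noise
    wear_truncation: float = 0.0     # µm of cuspal EDJ lost to wear
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_true < self.cft_true:
            raise ValueError("need 0 < ci_true < cft_true")
        if min(self.dsr_inner_mean, self.eer_schedule.initial, self.eer_schedule.floor) <= 0:
            raise ValueError("all rates must be positive")


def default_params(**overrides) -> GrowthParams:
    """Study-condition defaults: CFT 386 d, Ci 172 d, inner DSR 3.17 µm/day.

    The EDJ length is derived from the EER schedule so that recruitment
    covers it in exactly ``cft_true`` days (implied Cc = 214 d).
    """
    p = GrowthParams(**overrides)
    if p.edj_length == 0.0:
        p = replace(p, edj_length=float(p.eer_schedule.front(p.cft_true)))
    return p


@dataclass
class GroundTruth:
    """Exact chronology and fields of a simulated tooth."""

    cft: float
    ci: float
    cc: float
    segment_times: np.ndarray          # chain boundary times t_0=0 .. t_K=cft
    segment_arcs: np.ndarray           # EDJ arcs A(t_k)
    al_true_ages: dict                  # stria id -> days relative to birth
    first_chained_time: float = 0.0    # >0 when cuspal wear removed segments
    dsr_field: Callable = None         # (x µm, y µm) -> µm/day
    eer_rate: Callable = None          # t (days since initiation) -> µm/day
    front: Callable = None             # t -> EDJ arc µm
    params: GrowthParams = None

    def to_dict(self) -> dict:
        return {
            "cft": self.cft,
            "ci": self.ci,
            "cc": self.cc,
            "segment_times": [round(float(t), 6) for t in self.segment_times],
            "segment_arcs": [round(float(a), 6) for a in self.segment_arcs],
            "al_true_ages": {k: float(v) for k, v in self.al_true_ages.items()},
            "first_chained_time": float(self.first_chained_time),
        }


class _GrowthModel:
    """Internal growth field shared by tooth assembly and truth channel."""

    def __init__(self, params: GrowthParams, rng: np.random.Generator):
        self.p = params
        sched = params.eer_schedule
        implied_cft = sched.time_at_arc(params.edj_length)
        if abs(implied_cft - params.cft_true) > 0.005 * params.cft_true:
            raise ValueError(
                f"EER schedule covers {params.edj_length:.0f} µm of EDJ in "
                f"{implied_cft:.1f} days, inconsistent with cft_true={params.cft_true}"
            )
        self.cft = float(implied_cft)
        self.ci = params.ci_true
        # prenatal/postnatal step, normalized so the run-weighted mean
        # (runs are uniform in chain time) stays at dsr_inner_mean
        w_pre = self.ci / self.cft
        shift = params.postnatal_dsr_shift
        self.f_pre = 1.0 / (w_pre + (1.0 - w_pre) * (1.0 + shift))
        self.f_post = self.f_pre * (1.0 + shift)
        # smooth along-EDJ inner-DSR field: 3 random-phase cosines
        k = np.array([1.0, 2.0, 3.0])
        self.phases = rng.uniform(0, 2 * np.pi, size=3)
        self.amps = params.dsr_inner_rel_sd * np.sqrt(2.0 / 3.0) * np.ones(3)
        self.freqs = 2 * np.pi * k / params.edj_length
        self.gain = params.dsr_outer_gain / 1000.0   # per µm beyond the inner zone

    # -- fields ----------------------------------------------------------
    def inner_dsr_base(self, arc):
        """Inner-enamel DSR at EDJ arc position, before the birth step."""
        arc = np.asarray(arc)
        wig = sum(a * np.cos(f * arc + ph) for a, f, ph in
                  zip(self.amps, self.freqs, self.phases))
        return self.p.dsr_inner_mean * (1.0 + wig)

    def birth_factor(self, t):
        return np.where(np.asarray(t) < self.ci, self.f_pre, self.f_post)

    def effective_time(self, t0: float, t1: float) -> float:
        """Integral of the birth factor over [t0, t1]."""
        if t1 <= self.ci:
            return (t1 - t0) * self.f_pre
        if t0 >= self.ci:
            return (t1 - t0) * self.f_post
        return (self.ci - t0) * self.f_pre + (t1 - self.ci) * self.f_post

    def advance(self, t0: float, s: float) -> float:
        """Time at which effective time s has accrued since t0."""
        if t0 < self.ci:
            s_to_birth = (self.ci - t0) * self.f_pre
            if s <= s_to_birth:
                return t0 + s / self.f_pre
            return self.ci + (s - s_to_birth) / self.f_post
        return t0 + s / self.f_post

    def depth_at(self, tau: float, t: float) -> float:
        """Secretion depth (µm from EDJ) at time t of the ameloblast recruited at tau."""
        t = min(t, tau + self.p.secretion_span, self.cft)
        if t <= tau:
            return 0.0
        b = float(self.inner_dsr_base(self.p.eer_schedule.front(tau)))
        s = self.effective_time(tau, t)
        s0 = INNER_ZONE_UM / b
        if s <= s0:
            return b * s
        return INNER_ZONE_UM + (math.expm1(b * self.gain * (s - s0))) / self.gain

    def time_to_depth(self, tau: float, p: float) -> float:
        """Time at which the ameloblast recruited at tau reaches depth p."""
        b = float(self.inner_dsr_base(self.p.eer_schedule.front(tau)))
        if p <= INNER_ZONE_UM:
            s = p / b
        else:
            s = INNER_ZONE_UM / b + math.log1p(self.gain * (p - INNER_ZONE_UM)) / (b * self.gain)
        return self.advance(tau, s)

    # -- geometry --------------------------------------------------------
    def xy(self, arc, depth):
        """Section-plane position of (EDJ arc, prism depth); horn at angle 0."""
        theta = np.asarray(arc) / self.p.edj_radius
        r = self.p.edj_radius + np.asarray(depth)
        return np.stack([r * np.sin(theta), r * np.cos(theta)], axis=-1)

    def dsr_at(self, arc, depth) -> float:
        """Instantaneous true DSR at a spatial point, µm/day."""
        tau = self.p.eer_schedule.time_at_arc(float(arc))
        t = self.time_to_depth(tau, float(depth))
        b = float(self.inner_dsr_base(arc))
        f = self.f_pre if t < self.ci else self.f_post
        ramp = 1.0 if depth <= INNER_ZONE_UM else 1.0 + self.gain * (depth - INNER_ZONE_UM)
        return b * f * ramp

    def dsr_field_xy(self, x, y) -> float:
        """True DSR at planar coordinates (inverse of the radial geometry)."""
        r = math.hypot(x, y)
        theta = math.atan2(x, y)
        arc = theta * self.p.edj_radius
        depth = r - self.p.edj_radius
        arc = min(max(arc, 0.0), self.p.edj_length)
        return self.dsr_at(arc, max(depth, 0.0))

    def isochrone(self, t: float, n_points: int = 80) -> np.ndarray:
        """Polyline of the time-t growth front, outer enamel -> EDJ."""
        tau_min = max(0.0, t - self.p.secretion_span)
        taus = np.linspace(tau_min, t, n_points)
        arcs = self.p.eer_schedule.front(taus)
        depths = np.array([self.depth_at(tau, t) for tau in taus])
        return self.xy(arcs, depths)


def _chain_times(model: _GrowthModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact chain boundary times, EDJ arcs, and segment prism lengths."""
    times = [0.0]
    lengths = []
    t = 0.0
    while True:
        tau = t
        b = float(model.inner_dsr_base(model.p.eer_schedule.front(tau)))
        t_next = model.advance(tau, SEGMENT_UM / b)
        if t_next >= model.cft - 1e-9:
            final_len = b * model.effective_time(tau, model.cft)
            if final_len > 1e-6:
                times.append(model.cft)
                lengths.append(final_len)
            else:
                times[-1] = model.cft
            break
        times.append(t_next)
        lengths.append(SEGMENT_UM)
        t = t_next
    times = np.array(times)
    arcs = model.p.eer_schedule.front(times)
    return times, arcs, np.array(lengths)


def simulate_tooth(params: GrowthParams) -> tuple[ToothSection, GroundTruth]:
    """Grow one synthetic tooth section plus its exact ground truth.

    Deterministic for a given ``params.seed``. Raises ``ValueError``
    when the EER schedule cannot cover ``edj_length`` in ``cft_true``
    days (reporting the implied duration).
    """
    params = default_params() if params is None else params
    if params.edj_length == 0.0:
        params = default_params(**{
            f: getattr(params, f) for f in params.__dataclass_fields__
        })
    rng = np.random.default_rng(params.seed)
    model = _GrowthModel(params, rng)
    times, arcs, lengths = _chain_times(model)
    R = params.edj_radius

    # EDJ polyline, dentine horn -> cervix
    edj_pts = model.xy(np.linspace(0.0, params.edj_length, 400), 0.0)
    edj = Polyline(edj_pts)

    # enamel outline: outer surface (cusp -> cervix), then EDJ back to horn
    taus = np.linspace(0.0, model.cft, 200)
    surf = model.xy(
        params.eer_schedule.front(taus),
        [model.depth_at(tau, model.cft) for tau in taus],
    )
    ring = np.vstack([surf, edj_pts[::-1], surf[:1]])
    outline = Polyline(ring, dedup=True)

    # striae: chain terminals, NNL, ALs, periodic background
    striae: list[StriaTrace] = []
    for k, t_k in enumerate(times[1:-1], start=1):
        striae.append(StriaTrace(id=f"T{k}", kind="retzius",
                                 path=Polyline(model.isochrone(float(t_k)))))
    striae.append(StriaTrace(id="NNL", kind="neonatal",
                             path=Polyline(model.isochrone(model.ci))))
    al_true = {}
    for j, rel in enumerate(params.al_days, start=1):
        t_al = model.ci + rel
        if not 1.0 < t_al < model.cft - 1.0:
            continue
        sid = f"AL{j}"
        striae.append(StriaTrace(id=sid, kind="accentuated",
                                 path=Polyline(model.isochrone(t_al))))
        al_true[sid] = rel
    for m in range(1, int(model.cft / params.retzius_period)):
        t_r = m * params.retzius_period
        if min(abs(t_r - t) for t in times) < 0.5 or abs(t_r - model.ci) < 0.5:
            continue
        striae.append(StriaTrace(id=f"R{m}", kind="retzius",
                                 path=Polyline(model.isochrone(t_r, n_points=30))))

    # prism segment traces (radial) + cross-striation runs
    prisms: list[PrismSegmentTrace] = []
    runs: list[CrossStriationRun] = []
    for k, (t_k, L_k) in enumerate(zip(times[:-1], lengths), start=1):
        a_k = float(params.eer_schedule.front(t_k))
        path = Polyline(model.xy(a_k, np.linspace(0.0, L_k, 5)))
        start = model.xy(a_k, 0.0)
        terminal = f"T{k}" if k < len(lengths) else None
        prisms.append(PrismSegmentTrace(
            index=k, path=path, start_on_edj=Point2D(start[0], start[1]),
            terminal_stria=terminal,
        ))
        nr = params.runs_per_segment
        for i in range(nr):
            depth = (i + 0.5) / nr * L_k
            true_dsr = model.dsr_at(a_k, depth)
            n_str = int(rng.integers(6, 13))
            noise = 1.0 + params.noise_cv * rng.standard_normal() if params.noise_cv else 1.0
            runs.append(CrossStriationRun(
                segment_index=k,
                run_length=float(n_str * true_dsr * max(noise, 0.1)),
                n_striations=n_str,
            ))

    flags = SectionFlags()
    first_chained_time = 0.0
    if params.wear_truncation > 0.0:
        kept = [p for p in prisms if
                params.eer_schedule.front(times[p.index - 1]) >= params.wear_truncation]
        if not kept:
            raise ValueError("wear_truncation removes the whole chain")
        dropped = {p.index for p in prisms} - {p.index for p in kept}
        prisms = kept
        runs = [r for r in runs if r.segment_index not in dropped]
        flags.worn_horn = True
        first_chained_time = float(times[prisms[0].index - 1])

    section = ToothSection(
        id=f"SIM-{params.seed:04d}",
        site="synthetic",
        arch="lower",
        side="L",
        sex="unknown",
        wear_stage=2 if flags.worn_horn else 1,
        edj=edj,
        enamel_outline=outline,
        prisms=prisms,
        striae=striae,
        runs=runs,
        flags=flags,
    )
    truth = GroundTruth(
        cft=model.cft,
        ci=model.ci,
        cc=model.cft - model.ci,
        segment_times=times,
        segment_arcs=arcs,
        al_true_ages=al_true,
        first_chained_time=first_chained_time,
        dsr_field=model.dsr_field_xy,
        eer_rate=params.eer_schedule.rate,
        front=params.eer_schedule.front,
        params=params,
    )
    return section, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortJitter:
    """Between-tooth parameter spread (population sds of the study sample)."""

    cft_sd: float = 27.0
    ci_sd: float = 19.0
    dsr_mean_sd: float = 0.05


def make_cohort(
    n: int,
    jitter: Optional[CohortJitter] = None,
    seed: int = 0,
    arch_cft_means: Optional[tuple[float, float]] = None,
    arch_cft_sds: tuple[float, float] = (7.0, 14.0),
    base: Optional[GrowthParams] = None,
) -> list[tuple[ToothSection, GroundTruth]]:
    """Simulate a reproducible cohort of teeth with jittered parameters.

    With ``arch_cft_means=(upper, lower)`` the cohort alternates arches
    with arch-specific CFT means/sds (used for end-to-end two-sample
    power checks); otherwise CFT ~ N(base, cft_sd).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    jitter = jitter or CohortJitter()
    base = base or default_params()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if arch_cft_means is not None:
            arch = "upper" if i % 2 == 0 else "lower"
            mu, sd = (arch_cft_means[0], arch_cft_sds[0]) if arch == "upper" else (
                arch_cft_means[1], arch_cft_sds[1])
        else:
            arch, mu, sd = "lower", base.cft_true, jitter.cft_sd
        cft = float(np.clip(rng.normal(mu, sd), 250.0, 550.0))
        ci = float(np.clip(rng.normal(base.ci_true, jitter.ci_sd), 60.0, cft - 60.0))
        dsr = float(np.clip(rng.normal(base.dsr_inner_mean, jitter.dsr_mean_sd), 2.5, 4.0))
        child_seed = int(rng.integers(0, 2**31 - 1))
        p = replace(base, cft_true=cft, ci_true=ci, dsr_inner_mean=dsr,
                    edj_length=0.0, seed=child_seed)
        p = replace(p, edj_length=float(p.eer_schedule.front(p.cft_true)))
        section, truth = simulate_tooth(p)
        section.id = f"SIM-{seed:03d}-{i:03d}"
        section.arch = arch
        section.sex = "M" if rng.random() < 0.7 else "F"
        out.append((section, truth))
    return out


def sample_dsr_field(
    truth: GroundTruth,
    n: int = 400,
    noise_cv: float = 0.03,
    seed: int = 0,
):
    """Scattered DSR samples over the enamel cap, with exact truth.

    Returns ``(points, noisy_values, true_values)``: n sampling sites
    uniform in (recruitment time, relative depth), their noisy measured
    DSR, and the exact field value — the oracle for surface recovery.
    """
    rng = np.random.default_rng(seed)
    p = truth.params
    model = _GrowthModel(p, np.random.default_rng(p.seed))
    taus = rng.uniform(0.0, 0.98 * truth.cft, size=n)
    fracs = rng.uniform(0.02, 0.98, size=n)
    pts = np.empty((n, 2))
    true_vals = np.empty(n)
    for i, (tau, u) in enumerate(zip(taus, fracs)):
        arc = float(p.eer_schedule.front(tau))
        depth = u * model.depth_at(tau, truth.cft)
        pts[i] = model.xy(arc, depth)
        true_vals[i] = model.dsr_at(arc, depth)
    noisy = true_vals * (1.0 + noise_cv * rng.standard_normal(n)) if noise_cv else true_vals.copy()
    return pts, noisy, true_vals
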