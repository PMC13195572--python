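"""Stochastic and mean-field kinetics of the catalytic miRNA-cleavage cycle.

The cycle follows one nanostructure (TDN) site through: RNase H cleavage of
the integrated miRNA-mimic strand -> transient fraying of the retained 7-bp
segment exposes a toehold -> a free target miRNA binds the toehold ->
toehold-mediated displacement releases the 13-nt incumbent fragment -> the
bound target, now an RNA:DNA hybrid on the gapmer, is itself cleaved and its
fragments dissociate, regenerating the open site.  One site can therefore
turn over many targets.

RNase H is implicit (pseudo-first-order cleavage on eligible species); the
toehold open/close pair is constrained to the landscape's equilibrium,
k_open/k_close = exp(-delta_G_open/RT), and the committed displacement rate
comes from the landscape barrier through an Arrhenius-style prefactor.  All
rate constants are configurable placeholders, not fitted quantities.

Simulation is the exact stochastic simulation algorithm (Gillespie direct
method) with a deterministic mass-action ODE counterpart on the same
network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .thermo import DEFAULT_MODEL, EnergyModel

AVOGADRO = 6.02214076e23

CYCLE_SPECIES = (
    "TDN_intact",
    "TDN_cleaved_closed",
    "TDN_toehold_open",
    "TDN_target_bound",
    "TDN_target_duplex",
    "miR_free",
    "miR_cleaved",
    "fragment13_free",
)

_TDN_SITE_SPECIES = CYCLE_SPECIES[:5]
_TARGET_SPECIES = ("miR_free", "TDN_target_bound", "TDN_target_duplex", "miR_cleaved")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction with a stochastic rate constant (1/s for
    unimolecular; the bimolecular constant must already be divided by
    N_A * V so propensities are counts-based)."""

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"negative rate for reaction {self.name!r}")


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    initial: dict[str, int]
    conserved: tuple[dict[str, int], ...] = ()

    def __post_init__(self) -> None:
        for r in self.reactions:
            for sp in list(r.reactants) + list(r.products):
                if sp not in self.species:
                    raise ValueError(f"unknown species {sp!r} in reaction {r.name!r}")
        for vec in self.conserved:
            for r in self.reactions:
                delta = sum(
                    vec.get(sp, 0) * (r.products.get(sp, 0) - r.reactants.get(sp, 0))
                    for sp in self.species
                )
                if delta != 0:
                    raise ValueError(
                        f"reaction {r.name!r} violates declared conservation law"
                    )

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial.get(sp, 0) for sp in self.species], dtype=np.int64)

    def stoichiometry(self) -> np.ndarray:
        """(n_reactions, n_species) net change matrix."""
        S = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        idx = {sp: i for i, sp in enumerate(self.species)}
        for k, r in enumerate(self.reactions):
            for sp, n in r.reactants.items():
                S[k, idx[sp]] -= n
            for sp, n in r.products.items():
                S[k, idx[sp]] += n
        return S


@dataclass(frozen=True)
class CycleTrajectory:
    species: tuple[str, ...]
    times: np.ndarray
    counts: np.ndarray  # (n_times, n_species) integers
    seed: int
    firings: tuple[int, ...] = ()  # per-reaction event totals

    def series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def final(self, name: str) -> int:
        return int(self.series(name)[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "time_s", self.times)
        return df


@dataclass(frozen=True)
class RateParams:
    """Rate-constant placeholders for the catalytic cycle.

    ``k_cleave`` (1/s) pseudo-first-order RNase H cleavage on heteroduplex
    species; ``k_close`` (1/s) toehold re-closing; ``k_bind`` (1/(M s))
    bimolecular target binding converted through ``volume_L``;
    ``k_disp_prefactor`` (1/s) Arrhenius prefactor for the committed
    displacement step.  None of these is fitted to experiment.
    """

    k_cleave: float = 0.05
    k_close: float = 1e3
    k_bind: float = 1e6
    volume_L: float = 1.66e-16
    k_disp_prefactor: float = 1e2

    @property
    def c_bind(self) -> float:
        """Stochastic per-pair binding rate, 1/s."""
        return self.k_bind / (AVOGADRO * self.volume_L)


def build_cycle_network(
    delta_G_open: float,
    displacement_barrier: float,
    params: RateParams = RateParams(),
    n_tdn: int = 10,
    n_mir: int = 100,
    model: EnergyModel = DEFAULT_MODEL,
) -> ReactionNetwork:
    """Reaction network for the catalytic cycle.

    ``delta_G_open`` (kcal/mol) comes from the fraying landscape and fixes
    k_open = k_close * exp(-delta_G_open/RT) (thermodynamic consistency);
    ``displacement_barrier`` (kcal/mol) is the largest uphill step of the
    displacement landscape after toehold binding.
    """
    RT = model.RT
    k_open = params.k_close * math.exp(-delta_G_open / RT)
    k_disp = params.k_disp_prefactor * math.exp(-max(displacement_barrier, 0.0) / RT)
    reactions = (
        Reaction("rnaseh_cleave_tdn", {"TDN_intact": 1}, {"TDN_cleaved_closed": 1}, params.k_cleave),
        Reaction("toehold_open", {"TDN_cleaved_closed": 1}, {"TDN_toehold_open": 1}, k_open),
        Reaction("toehold_close", {"TDN_toehold_open": 1}, {"TDN_cleaved_closed": 1}, params.k_close),
        Reaction(
            "target_bind",
            {"TDN_toehold_open": 1, "miR_free": 1},
            {"TDN_target_bound": 1},
            params.c_bind,
        ),
        Reaction(
            "displacement",
            {"TDN_target_bound": 1},
            {"TDN_target_duplex": 1, "fragment13_free": 1},
            k_disp,
        ),
        Reaction(
            "rnaseh_cleave_target",
            {"TDN_target_duplex": 1},
            {"TDN_toehold_open": 1, "miR_cleaved": 1},
            params.k_cleave,
        ),
    )
    conserved = (
        {sp: 1 for sp in _TDN_SITE_SPECIES},
        {sp: 1 for sp in _TARGET_SPECIES},
    )
    return ReactionNetwork(
        species=CYCLE_SPECIES,
        reactions=reactions,
        initial={"TDN_intact": n_tdn, "miR_free": n_mir},
        conserved=conserved,
    )


def _propensities(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    idx = {sp: i for i, sp in enumerate(network.species)}
    a = np.empty(len(network.reactions))
    for k, r in enumerate(network.reactions):
        p = r.rate
        for sp, n in r.reactants.items():
            c = x[idx[sp]]
            for j in range(n):  # falling factorial for multi-copy reactants
                p *= max(c - j, 0)
            if n > 1:
                p /= math.factorial(n)
        a[k] = p
    return a


def gillespie_simulate(
    network: ReactionNetwork,
    t_end: float,
    seed: int = 0,
    max_events: int = 5_000_000,
    record_every: int = 1,
) -> CycleTrajectory:
    """Exact stochastic simulation (direct method), reproducible per seed.

    Records the state every ``record_every`` events plus the initial and
    final states; conservation laws hold at every recorded time because they
    hold eventwise.
    """
    rng = np.random.default_rng(seed)
    x = network.initial_vector().astype(np.int64)
    S = network.stoichiometry()
    idx = {sp: i for i, sp in enumerate(network.species)}
    react_idx = [
        [(idx[sp], n) for sp, n in r.reactants.items()] for r in network.reactions
    ]
    rates = np.array([r.rate for r in network.reactions])

    t = 0.0
    times = [0.0]
    states = [x.copy()]
    firings = np.zeros(len(network.reactions), dtype=np.int64)
    n_events = 0
    while t < t_end and n_events < max_events:
        a = rates.copy()
        for k, rl in enumerate(react_idx):
            for j, n in rl:
                c = x[j]
                for m in range(n):
                    a[k] *= max(c - m, 0)
                if n > 1:
                    a[k] /= math.factorial(n)
        a_total = a.sum()
        if a_total <= 0:
            break
        t += rng.exponential(1.0 / a_total)
        if t > t_end:
            break
        k = int(rng.choice(len(a), p=a / a_total))
        x += S[k]
        firings[k] += 1
        n_events += 1
        if n_events % record_every == 0:
            times.append(t)
            states.append(x.copy())
    times.append(t_end if t >= t_end or n_events >= max_events else t)
    states.append(x.copy())
    return CycleTrajectory(
        species=network.species,
        times=np.array(times),
        counts=np.vstack(states),
        seed=seed,
        firings=tuple(int(f) for f in firings),
    )


def ode_simulate(
    network: ReactionNetwork,
    t_end: float,
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Deterministic mass-action integration of the same network.

    Returns the scipy integration result with ``.t`` and ``.y`` (species in
    network order).  Integrator failures surface the scipy diagnostic.
    """
    S = network.stoichiometry().astype(float)
    idx = {sp: i for i, sp in enumerate(network.species)}
    terms = [
        (r.rate, [(idx[sp], n) for sp, n in r.reactants.items()])
        for r in network.reactions
    ]

    def rhs(_t, y):
        a = np.empty(len(terms))
        for k, (rate, rl) in enumerate(terms):
            p = rate
            for j, n in rl:
                p *= max(y[j], 0.0) ** n
            a[k] = p
        return a @ S

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        network.initial_vector().astype(float),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def check_conservation(network: ReactionNetwork, traj: CycleTrajectory) -> bool:
    """True iff every declared conservation total is exact at every recorded time."""
    x0 = network.initial_vector()
    idx = {sp: i for i, sp in enumerate(network.species)}
    for vec in network.conserved:
        w = np.zeros(len(network.species))
        for sp, coeff in vec.items():
            w[idx[sp]] = coeff
        totals = traj.counts @ w
        if not np.all(totals == float(x0 @ w)):
            return False
    return True


#: Waiting-state groups of the cycle, mapped to the step they feed.  The
#: closed and open states are lumped: time spent flickering between them is
#: time waiting for toehold presentation and target binding.
_CYCLE_WAIT_GROUPS = {
    "rnaseh_cleave_tdn": ("TDN_intact",),
    "toehold_presentation_and_binding": ("TDN_cleaved_closed", "TDN_toehold_open"),
    "displacement": ("TDN_target_bound",),
    "rnaseh_cleave_target": ("TDN_target_duplex",),
}


def rate_limiting_report(
    network: ReactionNetwork, traj: CycleTrajectory
) -> pd.DataFrame:
    """Per-reaction flux totals plus the flagged rate-limiting step.

    For the catalytic-cycle network the limiting step is the waiting-state
    group (time-integrated site occupancy, closed/open lumped as toehold
    presentation) where sites spend the largest share of post-initiation
    time; for other networks the reaction with the smallest firing total is
    flagged.
    """
    dt = np.diff(traj.times)
    t_total = traj.times[-1] - traj.times[0]
    rows = []
    for k, r in enumerate(network.reactions):
        fired = traj.firings[k] if traj.firings else 0
        rows.append(
            {
                "reaction": r.name,
                "rate_constant": r.rate,
                "firings": fired,
                "flux_per_s": fired / t_total if t_total > 0 else 0.0,
            }
        )
    df = pd.DataFrame(rows)

    is_cycle = all(sp in network.species for sp in CYCLE_SPECIES[:5])
    if is_cycle and t_total > 0:
        occ = {}
        for group, members in _CYCLE_WAIT_GROUPS.items():
            w = np.zeros(len(network.species))
            for sp in members:
                w[list(network.species).index(sp)] = 1.0
            series = traj.counts[:-1] @ w
            occ[group] = float((series * dt).sum())
        # the initial cleavage is a one-off activation, not part of the cycle
        cycle_occ = {g: v for g, v in occ.items() if g != "rnaseh_cleave_tdn"}
        limiting = max(cycle_occ, key=cycle_occ.get)

        def group_of(reaction_name: str) -> str:
            if reaction_name in ("toehold_open", "toehold_close", "target_bind"):
                return "toehold_presentation_and_binding"
            return reaction_name if reaction_name in occ else ""

        total_occ = sum(occ.values())
        df["waiting_time_share"] = [
            occ[g] / total_occ if (g := group_of(r)) else np.nan
            for r in df["reaction"]
        ]
        df["limiting"] = [group_of(r) == limiting for r in df["reaction"]]
    else:
        flagged = int(df["firings"].idxmin()) if len(df) > 1 else 0
        df["limiting"] = [i == flagged for i in range(len(df))]
    return df
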