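"""Reaction-diffusion model of precipitate formation in the degradation layer.

Dissolved species (Mg2+, OH-, H+, HCO3-, Ca2+, HPO4^2-) are transported by
diffusion (optionally with electro-migration closed by a zero-net-current
condition) on a 1-D domain spanning the porous degradation layer (DL) and
the electrolyte.  Mg2+ and OH- enter at the metal interface with the
sigmoid-gated dissolution flux of the quasi-1D model; one mole of H2 is
credited per mole of Mg dissolved (anodic/cathodic bookkeeping).

Six precipitates (brucite, magnesite, nesquehonite, portlandite, calcite,
hydroxyapatite) form only inside the DL with the bilinear rate law

    d c_p / dt = eps * k_l * (K_eq,l - c_i * c_j)

where c_i, c_j are the two rate-carrying species of reaction l.  Rate
constants are used signed, exactly as tabulated (physical growth under
supersaturation corresponds to negative k_l).  Each reaction step is taken
with a clamped backward-Euler solve of the reaction-extent equation, which
remains stable for arbitrarily stiff k_l and enforces nonnegativity of both
species and precipitates.

Equilibrium constants and the medium composition are not universal
constants of the model; the module ships a documented, overridable default
table emulating simulated body fluid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

from mguq.degradation_models.outputs import TimeSeriesOutput
from mguq.degradation_models.quasi1d import DAY, M_MG, RHO_MG

R_GAS = 8.314  # J / (mol K)
FARADAY = 96485.0  # C / mol

#: atomic masses, kg/mol
ATOMIC_MASS = {
    "C": 12.011e-3,
    "Ca": 40.078e-3,
    "P": 30.974e-3,
    "H": 1.008e-3,
    "O": 15.999e-3,
    "Mg": 24.305e-3,
}

ELEMENTS = ("C", "Ca", "P", "H", "O", "Mg")


@dataclass
class Species:
    """A dissolved species: charge, free diffusivity and initial level."""

    name: str
    z: int
    D: float  # m^2/s in the free electrolyte
    c0: float  # mol/m^3 initial concentration in the medium

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusivity of {self.name} must be > 0")
        if self.c0 < 0:
            raise ValueError(f"c0 of {self.name} must be >= 0")


@dataclass
class Reaction:
    """One precipitation reaction.

    ``rate_species`` are the two dissolved species whose concentration
    product drives the rate; ``stoich`` maps species name -> moles consumed
    (negative = produced) per mole of precipitate; ``elements`` maps element
    -> atoms per formula unit, used for the wt% bookkeeping.
    """

    name: str
    k: float  # signed backward rate constant, as tabulated
    K_eq: float
    rate_species: tuple[str, str]
    stoich: dict[str, float]
    elements: dict[str, int]

    def __post_init__(self) -> None:
        if self.K_eq < 0:
            raise ValueError(f"K_eq of {self.name} must be >= 0")
        for s in self.rate_species:
            if s not in self.stoich:
                raise ValueError(f"rate species {s} missing from stoichiometry of {self.name}")


def default_species() -> list[Species]:
    """Simulated-body-fluid-like medium (mol/m^3) at pH 7.4."""
    return [
        Species("Mg2+", 2, 0.706e-9, 1.5),
        Species("OH-", -1, 5.27e-9, 2.5e-4),
        Species("H+", 1, 9.31e-9, 4.0e-5),
        Species("HCO3-", -1, 1.18e-9, 4.2),
        Species("Ca2+", 2, 0.792e-9, 2.5),
        Species("HPO42-", -2, 0.69e-9, 1.0),
    ]


def default_reactions() -> list[Reaction]:
    """The six precipitates with tabulated optimal rate constants.

    K_eq values are synthetic defaults (not printed constants); they set
    the saturation thresholds of the bilinear rate law in (mol/m^3)^2.
    """
    return [
        Reaction(
            "brucite",
            -9.0245e-21,
            1e-2,
            ("Mg2+", "OH-"),
            {"Mg2+": 1, "OH-": 2},
            {"Mg": 1, "O": 2, "H": 2},
        ),
        Reaction(
            "magnesite",
            -7.0332e-9,
            1.0,
            ("Mg2+", "HCO3-"),
            {"Mg2+": 1, "HCO3-": 1, "H+": -1},
            {"Mg": 1, "C": 1, "O": 3},
        ),
        Reaction(
            "nesquehonite",
            -7.0023e-10,
            10.0,
            ("Mg2+", "HCO3-"),
            {"Mg2+": 1, "HCO3-": 1, "H+": -1},
            {"Mg": 1, "C": 1, "O": 6, "H": 6},
        ),
        Reaction(
            "portlandite",
            -1.0798e-2,
            1e2,
            ("Ca2+", "OH-"),
            {"Ca2+": 1, "OH-": 2},
            {"Ca": 1, "O": 2, "H": 2},
        ),
        Reaction(
            "calcite",
            -8.0037e-24,
            1.0,
            ("Ca2+", "HCO3-"),
            {"Ca2+": 1, "HCO3-": 1, "H+": -1},
            {"Ca": 1, "C": 1, "O": 3},
        ),
        # hydroxyapatite stoichiometry: 5 Ca2+ + 3 HPO4^2- + 4 OH- ->
        # Ca5(PO4)3OH + 3 H2O
        Reaction(
            "hydroxyapatite",
            9.001e16,
            1e-2,
            ("Ca2+", "HPO42-"),
            {"Ca2+": 5, "HPO42-": 3, "OH-": 4},
            {"Ca": 5, "P": 3, "O": 13, "H": 1},
        ),
    ]


@dataclass
class PrecipitationConfig:
    """Configuration of the precipitation (reaction-diffusion) model."""

    species: list[Species] = field(default_factory=default_species)
    reactions: list[Reaction] = field(default_factory=default_reactions)
    epsilon: float = 0.05
    temperature: float = 310.15  # K
    k_deg: float = -2.4321e-5  # mol m^-2 s^-1, signed as tabulated
    t_init: float = 1.932  # days
    #: diffusivity of every species inside the porous DL, m^2/s
    D_dl: float = 1.4e-16
    #: thickness of the degradation layer (precipitation region), m
    l_dl: float = 20e-6
    #: length of the electrolyte domain, m
    l_electrolyte: float = 0.2e-3
    #: Mg domain length, m (metal reservoir bookkeeping)
    r_initial: float = 0.2e-3
    migration_enabled: bool = False
    t_end: float = 28.0  # days
    n_t: int = 2000
    n_x: int = 40
    n_out: int = 29  # number of stored output times (incl. t=0)

    def __post_init__(self) -> None:
        if len(self.reactions) != 6:
            raise ValueError("exactly six precipitation reactions are required")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")
        if self.n_t < 2 or self.n_x < 4:
            raise ValueError("n_t >= 2 and n_x >= 4 required")
        names = {s.name for s in self.species}
        for r in self.reactions:
            for s in r.stoich:
                if s not in names:
                    raise ValueError(f"reaction {r.name} references unknown species {s}")

    def with_rate_constants(self, k: dict[str, float]) -> "PrecipitationConfig":
        """Copy of the config with reaction constants replaced by name."""
        reactions = [
            replace(r, k=k[r.name]) if r.name in k else replace(r) for r in self.reactions
        ]
        return replace(self, reactions=reactions)


@dataclass
class PrecipitationResult:
    """Fields and derived outputs of one precipitation run."""

    x: np.ndarray  # cell centres, m
    times: np.ndarray  # stored output times, days
    c: np.ndarray  # (n_out, n_species, n_x) dissolved fields
    c_p: np.ndarray  # (n_out, n_reactions, n_dl) precipitate fields
    wt: TimeSeriesOutput  # elemental wt% of the DL over time
    h2_evolved: np.ndarray  # (n_out,) cumulative H2, mol/m^2
    mg_dissolved_total: np.ndarray  # (n_out,) cumulative Mg released, mol/m^2
    metal_remaining: np.ndarray  # (n_out,) mol/m^2
    species_names: list[str]
    reaction_names: list[str]
    n_dl: int

    def mg_balance_error(self, config: PrecipitationConfig) -> float:
        """Relative closure error of total elemental Mg at the final time."""
        dx = self.x[1] - self.x[0]
        dissolved = self.c[-1, self.species_names.index("Mg2+")].sum() * dx
        n_mg = np.array([r.elements.get("Mg", 0) for r in config.reactions])
        precip = (self.c_p[-1] * n_mg[:, None]).sum() * dx
        total = dissolved + precip + self.metal_remaining[-1]
        initial = (
            config.r_initial * RHO_MG / M_MG
            + self.c[0, self.species_names.index("Mg2+")].sum() * dx
        )
        return abs(total - initial) / initial


def wt_percent(rho_elem: np.ndarray) -> np.ndarray:
    """Elemental weight percent: rho_i / sum(rho) * 100.

    ``rho_elem`` holds the six elemental mass concentrations of the DL in
    the order (C, Ca, P, H, O, Mg); must be nonnegative and not all zero.
    """
    rho = np.asarray(rho_elem, dtype=float)
    if rho.shape[-1] != 6:
        raise ValueError("expected six elemental mass concentrations (C, Ca, P, H, O, Mg)")
    if np.any(rho < 0):
        raise ValueError("mass concentrations must be nonnegative")
    total = rho.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("wt%% undefined when no mass is present")
    return rho / total * 100.0


def _reaction_extent(
    ci: np.ndarray,
    cj: np.ndarray,
    p: np.ndarray,
    ni: float,
    nj: float,
    a: float,
    K: float,
) -> np.ndarray:
    """Backward-Euler extent xi of one reaction over a step, per cell.

    Solves  xi = a * (K - (ci - ni*xi)*(cj - nj*xi))  with a = dt*eps*k
    (signed), then clamps xi into the physically admissible interval
    [-p, min(ci/ni, cj/nj)].  The quadratic is solved with the stable
    root selection that recovers the explicit rate as a -> 0.
    """
    # quadratic: A xi^2 + B xi + C = 0
    A = a * ni * nj
    B = 1.0 - a * (ni * cj + nj * ci)
    C = a * (ci * cj - K)
    xi = np.empty_like(ci)
    lin = np.abs(A) < 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        xi_lin = -C / B
    xi[lin] = np.where(np.isfinite(xi_lin[lin]), xi_lin[lin], 0.0)
    if not lin.all():
        m = ~lin
        disc = np.maximum(B[m] ** 2 - 4.0 * A * C[m], 0.0)
        sq = np.sqrt(disc)
        # root continuous with xi -> -C/B as A -> 0: the numerically stable
        # form xi = 2C / (-B - sign(B)*sq); if no real root exists (disc
        # clamped to 0) this degenerates to the vertex and is clamped below
        denom = -(B[m] + np.where(B[m] >= 0, 1.0, -1.0) * sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            root = 2.0 * C[m] / denom
        fallback = denom / (2.0 * A)  # companion root, used when denom ~ 0
        xi[m] = np.where(np.isfinite(root), root, fallback)
    hi = np.minimum(ci / ni if ni > 0 else np.inf, cj / nj if nj > 0 else np.inf)
    return np.clip(xi, -p, hi)


def simulate_precipitation(config: PrecipitationConfig) -> PrecipitationResult:
    """Run the transport-reaction system and return fields plus DL wt%."""
    n_x = config.n_x
    L = config.l_dl + config.l_electrolyte
    dx = L / n_x
    x = (np.arange(n_x) + 0.5) * dx
    n_dl = max(1, int(round(config.l_dl / dx)))
    dt = config.t_end * DAY / config.n_t

    names = [s.name for s in config.species]
    idx = {n: i for i, n in enumerate(names)}
    n_s = len(names)
    c = np.tile(np.array([s.c0 for s in config.species])[:, None], (1, n_x)).astype(float)
    p = np.zeros((len(config.reactions), n_dl))

    # face diffusivities: harmonic mean of cell values (DL cells use D_dl)
    solvers = []
    for s in config.species:
        D_cell = np.full(n_x, s.D)
        D_cell[:n_dl] = config.D_dl
        D_face = 2.0 * D_cell[:-1] * D_cell[1:] / (D_cell[:-1] + D_cell[1:])
        lam = dt / dx**2 * D_face  # length n_x - 1
        # backward-Euler tridiagonal (zero-flux at both ends, conservative)
        diag = 1.0 + np.concatenate([[lam[0]], lam[:-1] + lam[1:], [lam[-1]]])
        ab = np.zeros((3, n_x))
        ab[0, 1:] = -lam
        ab[1] = diag
        ab[2, :-1] = -lam
        solvers.append((ab, D_face))

    RT_F = R_GAS * config.temperature / FARADAY
    z = np.array([s.z for s in config.species], dtype=float)

    out_every = max(1, config.n_t // (config.n_out - 1))
    rec_t, rec_c, rec_p, rec_h2, rec_mg, rec_metal = [], [], [], [], [], []

    metal = config.r_initial * RHO_MG / M_MG  # mol/m^2
    mg_dissolved = 0.0
    i_mg, i_oh = idx["Mg2+"], idx["OH-"]

    def record(t_days: float) -> None:
        rec_t.append(t_days)
        rec_c.append(c.copy())
        rec_p.append(p.copy())
        rec_h2.append(mg_dissolved)  # 1 mol H2 per mol Mg
        rec_mg.append(mg_dissolved)
        rec_metal.append(metal)

    record(0.0)
    for step in range(config.n_t):
        t_days = (step + 0.5) * dt / DAY
        # --- dissolution source at the metal interface (first cell)
        flux = config.epsilon * abs(config.k_deg) / (
            1.0 + np.exp(-(t_days - config.t_init))
        )
        flux = min(flux, metal / dt)  # cannot dissolve more metal than remains
        c[i_mg, 0] += flux * dt / dx
        c[i_oh, 0] += 2.0 * flux * dt / dx
        metal -= flux * dt
        mg_dissolved += flux * dt

        # --- optional electro-migration (explicit, zero-net-current closure)
        if config.migration_enabled:
            cf = 0.5 * (c[:, :-1] + c[:, 1:])
            dcdx = (c[:, 1:] - c[:, :-1]) / dx
            D_faces = np.array([solvers[i][1] for i in range(n_s)])
            num = (z[:, None] * D_faces * dcdx).sum(axis=0)
            den = (z[:, None] ** 2 * D_faces * cf).sum(axis=0)
            dVdx = np.where(den > 0, RT_F * num / den, 0.0)
            mig = -z[:, None] * D_faces / RT_F * cf * dVdx  # flux per face
            upd = np.zeros_like(c)
            upd[:, :-1] -= mig * dt / dx
            upd[:, 1:] += mig * dt / dx
            c = np.maximum(c + upd, 0.0)

        # --- implicit diffusion, species by species
        for i in range(n_s):
            c[i] = solve_banded((1, 1), solvers[i][0], c[i])

        # --- precipitation, DL cells only, sequential over reactions
        for l, rxn in enumerate(config.reactions):
            a = dt * config.epsilon * rxn.k
            si, sj = rxn.rate_species
            ni, nj = rxn.stoich[si], rxn.stoich[sj]
            ci = c[idx[si], :n_dl]
            cj = c[idx[sj], :n_dl]
            xi = _reaction_extent(ci, cj, p[l], ni, nj, a, rxn.K_eq)
            # species not carrying the rate still obey stoichiometry; limit
            # the extent so that none of them goes negative
            for s_name, nu in rxn.stoich.items():
                if nu > 0:
                    xi = np.minimum(xi, c[idx[s_name], :n_dl] / nu)
            p[l] += xi
            for s_name, nu in rxn.stoich.items():
                c[idx[s_name], :n_dl] -= nu * xi
            np.maximum(c[:, :n_dl], 0.0, out=c[:, :n_dl])

        if (step + 1) % out_every == 0 or step == config.n_t - 1:
            record((step + 1) * dt / DAY)

    times = np.array(rec_t)
    c_hist = np.array(rec_c)
    p_hist = np.array(rec_p)

    # elemental mass concentrations of the DL from the precipitate fields
    mass_per_mol = np.array(
        [
            [r.elements.get(e, 0) * ATOMIC_MASS[e] for e in ELEMENTS]
            for r in config.reactions
        ]
    )  # (n_rxn, 6)
    rho_elem = np.einsum("tr,re->te", p_hist.mean(axis=2), mass_per_mol)
    total = rho_elem.sum(axis=1)
    wt_vals = np.full_like(rho_elem, np.nan)
    nz = total > 0
    wt_vals[nz] = rho_elem[nz] / total[nz, None] * 100.0

    # guard against duplicate trailing time point
    keep = np.concatenate([[True], np.diff(times) > 0])
    wt = TimeSeriesOutput(
        times=times[keep],
        values=wt_vals[keep],
        qoi_label="wt_percent",
        component_labels=list(ELEMENTS),
    )
    return PrecipitationResult(
        x=x,
        times=times[keep],
        c=c_hist[keep],
        c_p=p_hist[keep],
        wt=wt,
        h2_evolved=np.array(rec_h2)[keep],
        mg_dissolved_total=np.array(rec_mg)[keep],
        metal_remaining=np.array(rec_metal)[keep],
        species_names=names,
        reaction_names=[r.name for r in config.reactions],
        n_dl=n_dl,
    )
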