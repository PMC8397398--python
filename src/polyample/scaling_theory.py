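"""Scaling theory of Markov polyampholyte conformations.

A statistically neutral polyampholyte in a salt-free Theta solvent forms a
globule held together by Coulomb correlation attractions between oppositely
charged monomers.  A single quenched realization carries a characteristic net
charge Q = sqrt(f N Lambda), and when the Coulomb self-repulsion of that
charge exceeds the globule's surface energy (Rayleigh's criterion) the
globule splits into a necklace of beads joined by stretched strings.

Five conformational regimes follow from the competition, ordered by the
charge blockiness Lambda:

  I    Lambda < Lambda_a/r            spherical globule (near-alternating);
  II   Lambda_a/r  <= Lambda < Lambda_r/hb   necklace, N_bead ~ 1, charge in beads;
  III  Lambda_r/hb <= Lambda < Lambda_b/s    necklace, N_bead ~ u^(2/3) f^(1/3) Lambda,
                                       charge in beads;
  IV   Lambda_b/s  <= Lambda < Lambda_PE     necklace with the net charge migrated to
                                       the strings, N_bead ~ (f N / Lambda)^(1/2);
  V    Lambda >= Lambda_PE = f N       stretched polyelectrolyte.

All scaling prefactors are set to exactly 1, so branch intersections coincide
with the crossover formulas and the continuity of the chain size R across the
II/III, III/IV and IV/V boundaries holds as an exact identity.  Lengths are
in units of the monomer size a, energies in k_B T, charges in e.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ScalingParameters",
    "BlobSet",
    "RegimeBoundaries",
    "ConformationPrediction",
    "NecklaceFreeEnergy",
    "blob_sizes",
    "globule_density",
    "regime_boundaries",
    "rayleigh_ratio",
    "classify_regime",
    "predict_conformation",
    "necklace_free_energy",
    "minimize_necklace",
    "phase_diagram",
]

REGIMES = ("I", "II", "III", "IV", "V")


class ScaleSeparationWarning(UserWarning):
    """Crossover boundaries are out of order or a density exceeds unity."""


@dataclass(frozen=True)
class ScalingParameters:
    """Dimensionless inputs of the scaling theory.

    u      -- Bjerrum length l_B / a  (e^2 / (eps a k_B T)); positive.
    f      -- ionic fraction of monomers, 0 < f <= 1.
    N      -- chain length in monomers.
    Lambda -- block-charge parameter, >= 0 ((1+lam)/(1-lam) for Markov chains).
    """

    u: float
    f: float
    N: float
    Lambda: float

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("Bjerrum length u must be positive")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("ionic fraction f must lie in (0, 1]")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.Lambda < 0:
            raise ValueError("Lambda must be non-negative")
        if self.Lambda > self.f * self.N:
            warnings.warn(
                "Lambda exceeds f*N: the mean block is longer than the chain "
                "(polyelectrolyte regime V)",
                ScaleSeparationWarning,
                stacklevel=3,
            )

    @property
    def char_Q(self) -> float:
        """Characteristic global charge sqrt(f N Lambda), capped at f*N."""
        return min(math.sqrt(self.f * self.N * self.Lambda), self.f * self.N)


@dataclass(frozen=True)
class BlobSet:
    """Concentration / electrostatic blob sizes (units of a) and contents."""

    xi_a: float   # alternating-sequence concentration blob  a u^-2 f^-3/2
    xi_r: float   # random-sequence concentration blob       a / (u f Lambda)
    xi_hb: float  # highly blocky concentration blob         a (u f^2)^-1/3
    xi_e: float   # electrostatic blob (= xi_hb)
    g_e: float    # monomers per electrostatic blob          (u f^2)^-2/3
    q_e: float    # charge of the electrostatic blob         f * g_e


@dataclass(frozen=True)
class RegimeBoundaries:
    """Crossover blockiness values separating regimes I..V."""

    L_ar: float   # alternating -> substantially random:  u f^(1/2)
    L_rhb: float  # random -> highly blocky:              u^(-2/3) f^(-1/3) = q_e
    L_bs: float   # charge-in-beads -> charge-in-strings: u^(-4/9) f^(1/9) N^(1/3)
    L_pe: float   # necklace -> stretched PE:             f N

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.L_ar, self.L_rhb, self.L_bs, self.L_pe)


@dataclass(frozen=True)
class ConformationPrediction:
    """Regime label plus the full set of scaling observables (unit prefactors)."""

    regime: str
    R: float            # chain size, units a
    N_bead: float       # number of necklace beads (1 in I/II, 0 in V)
    m_bead: float       # monomers per bead
    m_str: float        # monomers per string
    D_bead: float       # bead diameter, units a
    l_str: float        # string length, units a
    L_nec: float        # necklace contour length, units a
    phi: float          # globule/bead volume fraction
    Q_bead: float       # net charge per bead, units e
    Q_str: float        # net charge per string, units e
    I_rayleigh: float   # destabilizing/stabilizing free-energy ratio


@dataclass(frozen=True)
class NecklaceFreeEnergy:
    """Scaling free energy of an (n_beads, charge-partition) necklace state."""

    F_coul_bead: float  # Coulomb self-energy of all beads
    F_surf: float       # surface energy of beads and strings
    F_el: float         # elastic stretching energy of strings
    F_coul_rep: float   # bead-bead + string Coulomb repulsion along strings
    n_beads: int
    q_str_frac: float
    m_bead: float
    m_str: float
    l_str: float
    D_bead: float

    @property
    def total(self) -> float:
        return self.F_coul_bead + self.F_surf + self.F_el + self.F_coul_rep


def blob_sizes(params: ScalingParameters) -> BlobSet:
    """Concentration and electrostatic blob scales for the three sequence classes."""
    u, f, Lam = params.u, params.f, params.Lambda
    xi_hb = (u * f * f) ** (-1.0 / 3.0)
    g_e = (u * f * f) ** (-2.0 / 3.0)
    return BlobSet(
        xi_a=u**-2 * f**-1.5,
        xi_r=math.inf if Lam == 0 else 1.0 / (u * f * Lam),
        xi_hb=xi_hb,
        xi_e=xi_hb,
        g_e=g_e,
        q_e=f * g_e,
    )


def globule_density(params: ScalingParameters) -> float:
    """Equilibrium monomer volume fraction phi of the (bead) globule.

    Piecewise over Lambda with unit prefactors:

      phi_a  = u^2 f^(3/2)        near-alternating (dipole attractions);
      phi_r  = u f Lambda         substantially random (charged-blob melt);
      phi_hb = (u f^2)^(1/3)      highly blocky (coacervate-like interior),
                                  independent of Lambda.

    Implemented as max(phi_a, min(phi_r, phi_hb)), which is continuous at both
    crossovers Lambda_a/r and Lambda_r/hb.  Values above 1 are capped with a
    warning (the theory leaves the dense limit open).
    """
    u, f, Lam = params.u, params.f, params.Lambda
    phi_a = u * u * f**1.5
    phi_r = u * f * Lam
    phi_hb = (u * f * f) ** (1.0 / 3.0)
    phi = max(phi_a, min(phi_r, phi_hb))
    if phi > 1.0:
        warnings.warn(
            f"globule density phi = {phi:.3g} > 1; capping at 1",
            ScaleSeparationWarning,
            stacklevel=2,
        )
        phi = 1.0
    return phi


def regime_boundaries(params: ScalingParameters) -> RegimeBoundaries:
    """The four crossover blockiness values (unit prefactors).

    L_ar solves phi_a = phi_r; L_rhb solves phi_r = phi_hb and equals the
    electrostatic-blob charge q_e; L_bs is where the bead charge, the block
    charge and the ionic content of a string coincide (Q/N_bead = Lambda =
    f m_str, using the regime-III laws); L_pe = f N is where the block length
    Lambda/f reaches the chain length.
    """
    u, f, N = params.u, params.f, params.N
    b = RegimeBoundaries(
        L_ar=u * math.sqrt(f),
        L_rhb=u ** (-2.0 / 3.0) * f ** (-1.0 / 3.0),
        L_bs=u ** (-4.0 / 9.0) * f ** (1.0 / 9.0) * N ** (1.0 / 3.0),
        L_pe=f * N,
    )
    if not (b.L_ar < b.L_rhb < b.L_bs < b.L_pe):
        warnings.warn(
            f"regime boundaries are not well separated for u={u}, f={f}, "
            f"N={N}: {b.as_tuple()}; scaling separation fails",
            ScaleSeparationWarning,
            stacklevel=2,
        )
    return b


def rayleigh_ratio(params: ScalingParameters) -> float:
    """Ratio I of globule-destabilizing to stabilizing free energies.

    I = (l_B Q^2 / R) / (R^2 / xi^2) with Q = sqrt(f N Lambda), the globule
    radius R = a (N/phi)^(1/3) and blob size xi = a/phi; algebraically
    I = u f Lambda / phi.  I << 1 in regime I (stable globule), I ~ 1 in II,
    and I >> 1 for highly blocky sequences.
    """
    phi = globule_density(params)
    return params.u * params.f * params.Lambda / phi


def classify_regime(params: ScalingParameters,
                    boundaries: Optional[RegimeBoundaries] = None) -> str:
    """Assign the conformational regime I..V on half-open intervals.

    [0, L_ar) -> I, [L_ar, L_rhb) -> II, [L_rhb, L_bs) -> III,
    [L_bs, L_pe) -> IV, [L_pe, inf) -> V; ties resolve to the lower regime
    boundary's upper side (left-closed intervals).
    """
    b = boundaries if boundaries is not None else regime_boundaries(params)
    Lam = params.Lambda
    edges = b.as_tuple()
    for label, hi in zip(REGIMES[:-1], edges):
        if Lam < hi:
            return label
    return "V"


def predict_conformation(params: ScalingParameters) -> ConformationPrediction:
    """Evaluate the full table of scaling laws for the regime of ``params``.

    All expressions carry unit prefactors.  The chain size R is continuous
    across the II/III, III/IV and IV/V boundaries as exact identities; the
    bead charge drops discontinuously by a factor (N/g_e)^(1/9) at III/IV,
    reflecting the migration of the net charge from beads to strings.
    """
    u, f, N, Lam = params.u, params.f, params.N, params.Lambda
    regime = classify_regime(params)
    phi = globule_density(params)
    Q = params.char_Q

    if regime == "I":
        R = N ** (1.0 / 3.0) / (u ** (2.0 / 3.0) * math.sqrt(f))
        pred = dict(R=R, N_bead=1.0, m_bead=float(N), m_str=0.0,
                    D_bead=R, l_str=0.0, L_nec=R,
                    Q_bead=Q, Q_str=0.0)
    elif regime == "II":
        R = math.sqrt(N)
        pred = dict(
            R=R, N_bead=1.0, m_bead=float(N),
            m_str=math.sqrt(N) / (u * f * Lam),
            D_bead=(N / (u * f * Lam)) ** (1.0 / 3.0),
            l_str=math.sqrt(N), L_nec=R,
            Q_bead=Q, Q_str=0.0,
        )
    elif regime == "III":
        N_bead = u ** (2.0 / 3.0) * f ** (1.0 / 3.0) * Lam
        R = u ** (1.0 / 3.0) * f ** (1.0 / 6.0) * math.sqrt(N * Lam)
        pred = dict(
            R=R, N_bead=N_bead, m_bead=N / N_bead,
            m_str=math.sqrt(N) / (u ** (2.0 / 3.0) * f ** (5.0 / 6.0) * math.sqrt(Lam)),
            D_bead=(N / (u * f * Lam)) ** (1.0 / 3.0),
            l_str=math.sqrt(N) / (u ** (1.0 / 3.0) * f ** (1.0 / 6.0) * math.sqrt(Lam)),
            L_nec=R,
            Q_bead=Q / N_bead, Q_str=0.0,
        )
    elif regime == "IV":
        N_bead = math.sqrt(f * N / Lam)
        R = u ** (1.0 / 3.0) * f ** (1.0 / 6.0) * math.sqrt(N * Lam)
        pred = dict(
            R=R, N_bead=N_bead,
            m_bead=math.sqrt(N * Lam / f),
            m_str=Lam / f,
            D_bead=(N * Lam) ** (1.0 / 6.0) / (u ** (1.0 / 9.0) * f ** (7.0 / 18.0)),
            l_str=(u / f) ** (1.0 / 3.0) * Lam,
            L_nec=R,
            Q_bead=(N * Lam) ** (1.0 / 6.0) / (u ** (4.0 / 9.0) * f ** (1.0 / 18.0)),
            Q_str=Lam,
        )
    else:  # V: stretched polyelectrolyte, one fully extended string
        R = u ** (1.0 / 3.0) * f ** (2.0 / 3.0) * N
        pred = dict(R=R, N_bead=0.0, m_bead=0.0, m_str=float(N),
                    D_bead=0.0, l_str=R, L_nec=R,
                    Q_bead=0.0, Q_str=f * N)

    return ConformationPrediction(
        regime=regime, phi=phi, I_rayleigh=rayleigh_ratio(params), **pred
    )


def necklace_free_energy(
    params: ScalingParameters,
    n_beads: int,
    q_str_frac: float,
) -> NecklaceFreeEnergy:
    """Scaling free energy of a necklace with ``n_beads`` beads and a fraction
    ``q_str_frac`` of the net charge Q = sqrt(f N Lambda) carried by strings.

    The necklace has n_beads strings of thickness xi = a/phi; the string
    length minimizes (l/xi + u (Q_bead^2 + Q_str^2)/l) in closed form, giving
    l* = sqrt(u xi (Q_bead^2 + Q_str^2)); the string mass follows from mass
    conservation m_str = phi l xi^2.  Energy terms, each in k_B T with unit
    prefactors:

      bead Coulomb self-energy   n_b * u Q_bead^2 / D_bead
      bead + string surface      n_b * (D_bead^2/xi^2 + l_str/xi)
      string elastic stretching  n_b * l_str/xi   (comparable to the surface
                                                   term for a string one blob
                                                   thick)
      Coulomb along the string   n_b * u (Q_bead^2 + Q_str^2) / l_str

    A string's net charge cannot exceed the block charge Lambda (the charge
    migrates by aligning a string with a single like-charge block), nor its
    ionic content f*m_str; partitions violating either cap, or leaving beads
    with non-positive mass, raise ValueError.  The single-bead neutral-string
    limit (n_beads=1, q_str_frac=0) reduces to the spherical-globule energies
    of the Rayleigh ratio.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if not (0.0 <= q_str_frac <= 1.0):
        raise ValueError("q_str_frac must lie in [0, 1]")
    u, N = params.u, params.N
    phi = globule_density(params)
    xi = 1.0 / phi
    Q = params.char_Q
    n_b = n_beads
    q_bead = (1.0 - q_str_frac) * Q / n_b
    q_str = q_str_frac * Q / n_b

    if n_b == 1 and q_str_frac == 0.0:
        D = (N / phi) ** (1.0 / 3.0)
        return NecklaceFreeEnergy(
            F_coul_bead=u * q_bead**2 / D,
            F_surf=(D / xi) ** 2,
            F_el=0.0,
            F_coul_rep=0.0,
            n_beads=1, q_str_frac=0.0,
            m_bead=float(N), m_str=0.0, l_str=0.0, D_bead=D,
        )

    if q_str > params.Lambda + 1e-12:
        raise ValueError(
            f"string charge {q_str:.3g} exceeds the block charge "
            f"Lambda = {params.Lambda:.3g}; migration infeasible"
        )
    q2 = q_bead**2 + q_str**2
    l_str = math.sqrt(u * xi * q2) if q2 > 0 else 0.0
    m_str = phi * l_str * xi**2
    if q_str > params.f * m_str + 1e-12 and m_str > 0:
        # stretch the string to hold its own charge at full ionic density
        m_str = q_str / params.f
        l_str = m_str / (phi * xi**2)
    m_bead = (N - n_b * m_str) / n_b
    if m_bead <= 0:
        raise ValueError(
            f"infeasible partition: strings exhaust the chain "
            f"(n_beads={n_b}, m_str={m_str:.3g}, N={N})"
        )
    D = (m_bead / phi) ** (1.0 / 3.0)
    surf = n_b * ((D / xi) ** 2 + (l_str / xi if l_str > 0 else 0.0))
    el = n_b * (l_str / xi if l_str > 0 else 0.0)
    rep = n_b * (u * q2 / l_str if l_str > 0 else 0.0)
    return NecklaceFreeEnergy(
        F_coul_bead=n_b * u * q_bead**2 / D,
        F_surf=surf,
        F_el=el,
        F_coul_rep=rep,
        n_beads=n_b, q_str_frac=q_str_frac,
        m_bead=m_bead, m_str=m_str, l_str=l_str, D_bead=D,
    )


def minimize_necklace(
    params: ScalingParameters,
    *,
    n_beads_max: Optional[int] = None,
    n_frac: int = 101,
    refine: bool = True,
) -> NecklaceFreeEnergy:
    """Grid-minimize the necklace free energy over (n_beads, q_str_frac).

    Dense logarithmic grid in the integer bead count and uniform grid in the
    string-charge fraction, with one local refinement pass around the coarse
    optimum.  Returns the minimizing :class:`NecklaceFreeEnergy`.
    """
    if n_beads_max is None:
        n_beads_max = max(4, int(2 * math.sqrt(params.N)))
    counts = np.unique(np.round(
        np.geomspace(1, n_beads_max, num=min(n_beads_max, 80))
    ).astype(int))
    fracs = np.linspace(0.0, 1.0, n_frac)

    def scan(count_list: Iterable[int], frac_list: Iterable[float]):
        best = None
        for nb in count_list:
            for x in frac_list:
                try:
                    fe = necklace_free_energy(params, int(nb), float(x))
                except ValueError:
                    continue
                if best is None or fe.total < best.total:
                    best = fe
        return best

    best = scan(counts, fracs)
    if best is None:
        raise ValueError("no feasible necklace state on the search grid")
    if refine:
        lo = max(1, best.n_beads - 5)
        hi = min(n_beads_max, best.n_beads + 5)
        dx = 1.0 / (n_frac - 1)
        fr = np.clip(np.linspace(best.q_str_frac - dx, best.q_str_frac + dx, 21),
                     0.0, 1.0)
        refined = scan(range(lo, hi + 1), np.unique(fr))
        if refined is not None and refined.total < best.total:
            best = refined
    return best


def phase_diagram(
    u: float,
    f: float,
    N: float,
    Lambda_grid: Iterable[float],
) -> pd.DataFrame:
    """Tabulate regime labels and scaling observables over a Lambda grid.

    Returns a DataFrame with one row per Lambda, columns ``regime`` plus every
    :class:`ConformationPrediction` observable.  N_bead(Lambda) rises linearly
    through regime III, peaks at Lambda_b/s, and falls as Lambda^(-1/2) in IV;
    R(Lambda) is non-decreasing above Lambda_a/r.
    """
    grid = np.asarray(list(Lambda_grid), dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("Lambda grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("Lambda grid must be strictly increasing")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ScaleSeparationWarning)
        for Lam in grid:
            p = ScalingParameters(u=u, f=f, N=N, Lambda=float(Lam))
            pred = predict_conformation(p)
            rows.append({"Lambda": Lam, **pred.__dict__})
    return pd.DataFrame(rows)
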