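"""Synthetic inputs with the statistical structure each analysis stage assumes.

Four generators mirror the four kinds of experimental input so the full
screening pipeline and its parameter-recovery tests run without external
data:

* growth curves — lag, then logistic growth sampled every 24 h for seven
  days (the assay design), with multiplicative lognormal noise;
* FAME profiles — compositions on the 100-wt% simplex with phylotype block
  structure (a Dirichlet base per phylotype, log-scale jitter per strain);
* copper dose-response panels — replicate fluorescence time courses whose
  underlying rates follow a log-logistic (Hill) inhibition curve
  mu(c) = mu0 / (1 + (c/EC50)^h), with a zero-growth floor;
* alignments — sequences evolved under Jukes-Cantor on a random bifurcating
  tree, with injected gap columns and near-identical tip pairs.

Randomness is fully determined by the config seed; per-strain/taxon
sub-streams are derived with ``numpy.random.SeedSequence`` spawn keys so
adding a strain never reshuffles the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioassay import DoseResponsePanel
from .fame import FameProfile
from .growth import GrowthCurve
from .phylo import Alignment

from skbio import TreeNode

__all__ = [
    "GrowthSimConfig",
    "FameSimConfig",
    "DoseSimConfig",
    "AlignSimConfig",
    "simulate_growth_curve",
    "simulate_fame_profiles",
    "simulate_dose_response",
    "simulate_alignment",
    "DEFAULT_SPECIES_POOL",
]

#: seven fatty acids typical of green-microalgal FAME profiles
DEFAULT_SPECIES_POOL = (
    "C12:0", "C16:0", "C16:4(n-3)", "C18:0", "C18:1", "C18:2", "C20:4",
)

_NUCLEOTIDES = np.array(list("ACGT"))


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class GrowthSimConfig:
    """Lag + logistic growth sampled on the seven-day, 24-h assay grid."""

    mu_true: float = 0.7  # d^-1
    n0: float = 1e4  # initial density (cells/mL or OD units)
    carrying_capacity: float = 1e7  # same units as n0; may be inf
    lag_h: float = 0.0
    noise_cv: float = 0.0
    sample_interval_h: float = 24.0
    duration_h: float = 168.0
    seed: int = 0
    strain_id: str = "sim"

    def __post_init__(self) -> None:
        if self.mu_true < 0:
            raise ValueError("mu_true must be >= 0")
        if self.n0 <= 0 or self.carrying_capacity < self.n0:
            raise ValueError("need 0 < n0 <= carrying_capacity")
        if self.lag_h < 0 or self.noise_cv < 0 or self.sample_interval_h <= 0:
            raise ValueError("lag_h, noise_cv >= 0 and sample_interval_h > 0 required")
        if self.duration_h / self.sample_interval_h < 3:
            raise ValueError("need at least 3 sampling intervals to fit")


def _logistic_density(cfg: GrowthSimConfig, t_h: np.ndarray) -> np.ndarray:
    tau_days = np.maximum(t_h - cfg.lag_h, 0.0) / 24.0
    growth = np.exp(cfg.mu_true * tau_days)
    k = cfg.carrying_capacity
    if math.isinf(k):
        return cfg.n0 * growth
    return k * cfg.n0 * growth / (k + cfg.n0 * (growth - 1.0))


def simulate_growth_curve(cfg: GrowthSimConfig) -> tuple[GrowthCurve, dict]:
    """One strain's density time series plus the true generating parameters.

    Density holds at n0 through the lag, then follows logistic growth with
    intrinsic rate mu_true toward the carrying capacity; multiplicative
    lognormal noise of the configured CV is applied point-wise (density
    stays positive by construction).
    """
    times = np.arange(0.0, cfg.duration_h + 1e-9, cfg.sample_interval_h)
    dens = _logistic_density(cfg, times)
    dens = dens * _lognormal_factors(_rng(cfg.seed), cfg.noise_cv, len(times))
    curve = GrowthCurve(
        strain_id=cfg.strain_id,
        times=tuple(times),
        densities=tuple(dens),
        measure="od550",
    )
    truth = {
        "mu_true": cfg.mu_true,
        "n0": cfg.n0,
        "carrying_capacity": cfg.carrying_capacity,
        "lag_h": cfg.lag_h,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# FAME profiles


@dataclass(frozen=True)
class FameSimConfig:
    """Phylotype-structured compositional profiles over a fatty-acid pool."""

    n_phylotypes: int = 3
    strains_per_phylotype: int = 3
    species_pool: tuple[str, ...] = DEFAULT_SPECIES_POOL
    base_concentration: float = 1.0  # Dirichlet concentration per species
    within_phylotype_sd: float = 0.1  # log-scale jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phylotypes < 1 or self.strains_per_phylotype < 1:
            raise ValueError("counts must be >= 1")
        if not self.species_pool:
            raise ValueError("species_pool must be non-empty")
        if self.base_concentration <= 0 or self.within_phylotype_sd < 0:
            raise ValueError("base_concentration > 0 and sd >= 0 required")


def simulate_fame_profiles(
    cfg: FameSimConfig,
) -> tuple[list[FameProfile], dict[str, int]]:
    """Profiles with phylotype block structure, plus the true labels.

    Each phylotype draws a base composition from a symmetric Dirichlet;
    member strains multiply it by componentwise lognormal jitter of the
    configured log-scale SD and renormalise to 100 wt%. SD = 0 makes all
    members of a phylotype identical.
    """
    pool = list(cfg.species_pool)
    profiles: list[FameProfile] = []
    labels: dict[str, int] = {}
    for p in range(cfg.n_phylotypes):
        base = _rng(cfg.seed, p, 0).dirichlet(
            np.full(len(pool), cfg.base_concentration)
        )
        for s in range(cfg.strains_per_phylotype):
            jitter = (
                np.exp(_rng(cfg.seed, p, s + 1).normal(0.0, cfg.within_phylotype_sd, len(pool)))
                if cfg.within_phylotype_sd > 0
                else np.ones(len(pool))
            )
            w = base * jitter
            w = 100.0 * w / w.sum()
            sid = f"P{p + 1}S{s + 1}"
            profiles.append(
                FameProfile(strain_id=sid, abundances=dict(zip(pool, w)))
            )
            labels[sid] = p + 1
    return profiles, labels


# ---------------------------------------------------------------------------
# dose-response panels


@dataclass(frozen=True)
class DoseSimConfig:
    """Log-logistic copper inhibition with triplicate fluorescence curves."""

    mu0: float = 1.0  # control growth rate, d^-1
    ec50: float = 0.3  # mg/L
    hill: float = 2.0
    concentrations: tuple[float, ...] = (0.01, 0.1, 0.32, 1.0, 3.2)
    reps: int = 3
    noise_cv: float = 0.0
    growth_floor: float = 0.05  # d^-1; below this the culture is non-growing
    f0: float = 100.0  # initial fluorescence, arbitrary units
    duration_h: float = 72.0
    seed: int = 0
    strain_id: str = "sim"

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("mu0, ec50, hill must be > 0")
        if list(self.concentrations) != sorted(self.concentrations):
            raise ValueError("concentrations must be sorted ascending")
        if self.reps < 1 or self.noise_cv < 0:
            raise ValueError("reps >= 1 and noise_cv >= 0 required")


def hill_rate(cfg: DoseSimConfig, c: float) -> float:
    """Mean growth rate mu0 / (1 + (c/EC50)^h); mu0 at c = 0, mu0/2 at EC50."""
    if c == 0:
        return cfg.mu0
    return cfg.mu0 / (1.0 + (c / cfg.ec50) ** cfg.hill)


def simulate_dose_response(cfg: DoseSimConfig) -> tuple[DoseResponsePanel, dict]:
    """A replicate panel of fluorescence curves plus the true parameters.

    Replicate rates are the Hill mean times lognormal noise; rates below
    the growth floor produce flat (zero-growth) fluorescence. The control
    (0 mg/L) is always included. Mean rates are non-increasing in
    concentration before noise.
    """
    concs = (0.0,) + tuple(c for c in cfg.concentrations if c != 0.0)
    times = np.arange(0.0, cfg.duration_h + 1e-9, 24.0)
    rows = []
    true_rates: dict[float, float] = {}
    for ci, c in enumerate(concs):
        mean_rate = hill_rate(cfg, c)
        if mean_rate < cfg.growth_floor:
            mean_rate = 0.0
        true_rates[c] = mean_rate
        factors = _lognormal_factors(_rng(cfg.seed, ci), cfg.noise_cv, cfg.reps)
        for rep in range(cfg.reps):
            rate = mean_rate * factors[rep]
            fluor = cfg.f0 * np.exp(rate * times / 24.0)
            for t, f in zip(times, fluor):
                rows.append(
                    {
                        "concentration_mg_L": c,
                        "replicate": rep + 1,
                        "time_h": t,
                        "fluorescence": f,
                    }
                )
    panel = DoseResponsePanel(strain_id=cfg.strain_id, data=pd.DataFrame(rows))
    c_mean = true_rates[0.0]
    truth = {
        "mu0": cfg.mu0,
        "ec50": cfg.ec50,
        "hill": cfg.hill,
        "true_rates": true_rates,
        "true_percent_inhibition": {
            c: (c_mean - r) / c_mean * 100.0 for c, r in true_rates.items()
        },
    }
    return panel, truth


# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class AlignSimConfig:
    """Jukes-Cantor evolution on a random bifurcating tree, with gap columns."""

    n_taxa: int = 8
    seq_length: int = 1000
    subs_rate: float = 0.05  # expected substitutions/site per branch
    gap_column_fraction: float = 0.0
    phylotype_pairs: int = 0  # tips duplicated at near-zero divergence
    twin_branch_length: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.seq_length < 1 or self.subs_rate < 0:
            raise ValueError("seq_length >= 1 and subs_rate >= 0 required")
        if not (0 <= self.gap_column_fraction < 1):
            raise ValueError("gap_column_fraction must lie in [0, 1)")
        if self.phylotype_pairs < 0 or self.phylotype_pairs > self.n_taxa:
            raise ValueError("0 <= phylotype_pairs <= n_taxa required")


def _random_topology(n_taxa: int, rng: np.random.Generator, branch_rng) -> TreeNode:
    """Random bifurcating tree by successive random joins."""
    nodes = [TreeNode(name=f"T{i + 1}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(branch_rng())
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(branch_rng())
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    root.length = None
    return root


def _evolve_jc(
    parent_seq: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes-Cantor: each site differs from its parent with the JC probability."""
    if branch_length <= 0:
        return parent_seq.copy()
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))
    seq = parent_seq.copy()
    hit = rng.random(len(seq)) < p_diff
    n_hit = int(hit.sum())
    if n_hit:
        # substitute to one of the three *other* bases, uniformly
        offsets = rng.integers(1, 4, size=n_hit)
        seq[hit] = (seq[hit] + offsets) % 4
    return seq


def simulate_alignment(cfg: AlignSimConfig) -> tuple[Alignment, TreeNode]:
    """A rectangular alignment evolved on a known tree, plus that true tree.

    Branch lengths are exponential with mean ``subs_rate``. After
    evolution, the first ``phylotype_pairs`` tips get a near-identical twin
    (attached at ``twin_branch_length`` per side), and each column is
    independently turned into a gap column with probability
    ``gap_column_fraction`` (a random non-empty subset of taxa gapped).
    """
    top_rng = _rng(cfg.seed, 0)
    branch_rng = lambda: top_rng.exponential(cfg.subs_rate) if cfg.subs_rate > 0 else 0.0
    tree = _random_topology(cfg.n_taxa, top_rng, branch_rng)

    # twin tips for phylotype structure
    for k in range(cfg.phylotype_pairs):
        tip = tree.find(f"T{k + 1}")
        twin_len = cfg.twin_branch_length if cfg.subs_rate > 0 else 0.0
        old_len = tip.length
        a = TreeNode(name=tip.name, length=twin_len)
        b = TreeNode(name=f"{tip.name}twin", length=twin_len)
        tip.name = None
        tip.append(a)
        tip.append(b)
        tip.length = old_len

    root_seq = _rng(cfg.seed, 1).integers(0, 4, size=cfg.seq_length)
    seqs: dict[str, np.ndarray] = {}

    def _descend(node: TreeNode, seq: np.ndarray, path: tuple[int, ...]) -> None:
        for k, child in enumerate(node.children):
            child_seq = _evolve_jc(
                seq, child.length or 0.0, _rng(cfg.seed, 2, *path, k)
            )
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                _descend(child, child_seq, path + (k,))

    _descend(tree, root_seq, ())

    ids = sorted(seqs)
    rows = np.array([seqs[i] for i in ids])
    chars = _NUCLEOTIDES[rows]

    gap_rng = _rng(cfg.seed, 3)
    if cfg.gap_column_fraction > 0:
        gap_cols = gap_rng.random(cfg.seq_length) < cfg.gap_column_fraction
        for j in np.nonzero(gap_cols)[0]:
            n_gapped = int(gap_rng.integers(1, len(ids)))
            who = gap_rng.choice(len(ids), size=n_gapped, replace=False)
            chars[who, j] = "-"

    aln = Alignment(ids=tuple(ids), seqs=tuple("".join(r) for r in chars))
    return aln, tree
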