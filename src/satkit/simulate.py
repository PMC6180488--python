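"""Synthetic sparse UMI count matrices with planted hierarchical cluster structure.

The generator draws gamma-Poisson (negative-binomial) counts around a
log-normal baseline expression profile. Cells belong to broad types, each
optionally containing subtypes; a type shifts a random block of "program"
genes up by a configurable fold, and each subtype additionally up-regulates
a set of exclusive marker genes. Dedicated gene blocks named with the mouse
mitochondrial ("mt-") and ribosomal ("Rps"/"Rpl") prefixes receive per-cell
means matched to drawn mito/ribo target fractions so QC code paths run on
simulated data unmodified. Library labels are assigned round-robin, which a
uniform random subsample preserves proportionally.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import SatkitError
from .io import CountMatrix

__all__ = ["BroadType", "Subtype", "SimConfig", "simulate", "plant_rare_population"]


@dataclass
class Subtype:
    name: str
    frequency: float  # within the parent broad type
    shift: float = 0.8  # log-fold magnitude of the subtype program
    n_markers: int = 10  # exclusive marker genes
    marker_fc: float = 4.0  # linear fold change of the exclusive markers


@dataclass
class BroadType:
    name: str
    frequency: float
    shift: float = 1.5  # log-fold magnitude of the broad-type program
    subtypes: list[Subtype] = field(default_factory=list)


def _default_types() -> list[BroadType]:
    # five broad types, one carrying two subtypes, mirroring a tissue with
    # abundant classes and finer structure inside one of them
    return [
        BroadType("A", 0.30, subtypes=[Subtype("A1", 0.5), Subtype("A2", 0.5)]),
        BroadType("B", 0.25),
        BroadType("C", 0.20),
        BroadType("D", 0.15),
        BroadType("E", 0.10),
    ]


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults model a modest droplet experiment: 2000 cells, 500 genes of
    which 13 are mitochondrial and 40 ribosomal, ~5000 UMIs per cell
    (log-normal depth), mito/ribo fractions centered at 5%, negative-binomial
    dispersion theta = 10, five broad types with 50-gene programs shifted
    by ~e^1.5 per gene.

    Besides the type programs, every cell expresses ``n_noise_programs``
    shared latent gene programs with standard-normal per-cell activities.
    These model type-independent biological state (cell cycle, stress,
    metabolism) and give the data the moderately high-dimensional
    within-type structure that real atlases show — without them the
    significant-PC space would collapse onto the few between-type axes.
    """

    n_cells: int = 2000
    n_genes: int = 500
    broad_types: list[BroadType] = field(default_factory=_default_types)
    n_program_genes: int = 50
    n_noise_programs: int = 15
    noise_program_genes: int = 50
    noise_amplitude: float = 0.4  # log-scale activity scale of latent programs
    nb_dispersion: float = 10.0  # gamma shape; larger = closer to Poisson
    depth_log_mean: float = np.log(5000.0)
    depth_log_sd: float = 0.3
    mito_frac_mean: float = 0.05
    mito_frac_sd: float = 0.02
    ribo_frac_mean: float = 0.05
    ribo_frac_sd: float = 0.02
    n_mito_genes: int = 13
    n_ribo_genes: int = 40
    n_libraries: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(t.frequency for t in self.broad_types)
        if abs(total - 1.0) > 1e-6:
            raise SatkitError(f"broad-type frequencies sum to {total}, not 1")
        for t in self.broad_types:
            if t.subtypes:
                s = sum(st.frequency for st in t.subtypes)
                if abs(s - 1.0) > 1e-6:
                    raise SatkitError(
                        f"subtype frequencies of {t.name!r} sum to {s}, not 1"
                    )

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "broad_types" in raw:
            raw["broad_types"] = [
                BroadType(
                    name=t["name"],
                    frequency=t["frequency"],
                    shift=t.get("shift", 1.5),
                    subtypes=[Subtype(**st) for st in t.get("subtypes", [])],
                )
                for t in raw["broad_types"]
            ]
        return cls(**raw)


def _gene_names(cfg: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    n_plain = cfg.n_genes - cfg.n_mito_genes - cfg.n_ribo_genes
    if n_plain <= 0:
        raise SatkitError("n_genes too small for the mito/ribo blocks")
    names = (
        [f"Gene{i}" for i in range(n_plain)]
        + [f"mt-Sim{i}" for i in range(cfg.n_mito_genes)]
        + [f"Rps{i}" for i in range(cfg.n_ribo_genes)]
    )
    mito = np.zeros(cfg.n_genes, dtype=bool)
    mito[n_plain : n_plain + cfg.n_mito_genes] = True
    ribo = np.zeros(cfg.n_genes, dtype=bool)
    ribo[n_plain + cfg.n_mito_genes :] = True
    return names, mito, ribo


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson counts with mean ``mean`` and variance mean + mean^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def simulate(config: SimConfig | None = None) -> CountMatrix:
    """Draw a synthetic :class:`CountMatrix` with truth labels at both levels.

    ``truth_labels`` holds the subtype-level label (``A/A1``); the broad
    label is its prefix. Counts are integer, non-negative and sparse;
    per-cell depth, mito and ribo fractions follow the configured
    distributions in expectation.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    names, mito_mask, ribo_mask = _gene_names(cfg)
    plain_mask = ~(mito_mask | ribo_mask)
    n_plain = int(plain_mask.sum())

    # baseline relative expression of the non-mito/ribo genes
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    # within-block baseline shape for mito and ribo genes
    baseline[mito_mask] = rng.lognormal(0.0, 0.5, cfg.n_mito_genes)
    baseline[ribo_mask] = rng.lognormal(0.0, 0.5, cfg.n_ribo_genes)

    # build per-(sub)type mean multipliers on the plain genes
    plain_idx = np.where(plain_mask)[0]
    leaf_names: list[str] = []
    leaf_freqs: list[float] = []
    leaf_factor: list[np.ndarray] = []
    used_markers: set[int] = set()
    for bt in cfg.broad_types:
        prog = rng.choice(plain_idx, size=min(cfg.n_program_genes, n_plain), replace=False)
        base_factor = np.ones(cfg.n_genes)
        base_factor[prog] = np.exp(bt.shift * rng.standard_normal(prog.size))
        subtypes = bt.subtypes or [Subtype(name="", frequency=1.0, shift=0.0, n_markers=0)]
        for st in subtypes:
            factor = base_factor.copy()
            if st.shift > 0:
                sub_prog = rng.choice(plain_idx, size=min(cfg.n_program_genes // 2, n_plain), replace=False)
                factor[sub_prog] *= np.exp(st.shift * rng.standard_normal(sub_prog.size))
            if st.n_markers > 0:
                free = np.array(sorted(set(plain_idx) - used_markers))
                mk = rng.choice(free, size=st.n_markers, replace=False)
                used_markers.update(mk.tolist())
                factor[mk] *= st.marker_fc
            leaf_names.append(f"{bt.name}/{st.name}" if st.name else bt.name)
            leaf_freqs.append(bt.frequency * st.frequency)
            leaf_factor.append(factor)

    freqs = np.asarray(leaf_freqs)
    expected = freqs * cfg.n_cells
    if (expected < 1).any():
        warnings.warn("some (sub)type expected sizes are below 1 cell")
    leaf_of_cell = rng.choice(len(leaf_names), size=cfg.n_cells, p=freqs)

    depth = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, cfg.n_cells)
    mito_target = np.clip(
        rng.normal(cfg.mito_frac_mean, cfg.mito_frac_sd, cfg.n_cells), 0.0, 0.5
    )
    ribo_target = np.clip(
        rng.normal(cfg.ribo_frac_mean, cfg.ribo_frac_sd, cfg.n_cells), 0.0, 0.5
    )

    # plain-gene mean matrix (genes x cells): type factor x latent-program factor
    plain_mean = baseline[:, None] * np.stack(leaf_factor, axis=1)[:, leaf_of_cell]
    plain_mean[~plain_mask, :] = 0.0
    if cfg.n_noise_programs > 0 and cfg.noise_amplitude > 0:
        log_noise = np.zeros((cfg.n_genes, cfg.n_cells))
        for _ in range(cfg.n_noise_programs):
            prog = rng.choice(plain_idx, size=min(cfg.noise_program_genes, n_plain), replace=False)
            direction = rng.standard_normal(prog.size)
            activity = rng.standard_normal(cfg.n_cells)
            log_noise[prog] += cfg.noise_amplitude * np.outer(direction, activity)
        plain_mean *= np.exp(log_noise)

    mito_profile = np.where(mito_mask, baseline, 0.0)
    ribo_profile = np.where(ribo_mask, baseline, 0.0)
    # allocate each cell's depth across the three blocks by its target fractions
    plain_share = 1.0 - mito_target - ribo_target
    mean_total = (
        plain_mean / plain_mean.sum(axis=0, keepdims=True) * plain_share
        + np.outer(mito_profile / mito_profile.sum(), mito_target)
        + np.outer(ribo_profile / ribo_profile.sum(), ribo_target)
    ) * depth
    counts = sp.csc_matrix(_nb_draw(rng, mean_total, cfg.nb_dispersion))

    barcodes = [f"CELL{i:06d}" for i in range(cfg.n_cells)]
    libraries = [f"lib{i % cfg.n_libraries}" for i in range(cfg.n_cells)]
    truth = [leaf_names[j] for j in leaf_of_cell]
    return CountMatrix(
        counts=counts,
        gene_names=names,
        barcodes=barcodes,
        library_labels=libraries,
        truth_labels=truth,
    )


def plant_rare_population(
    matrix: CountMatrix,
    frequency: float,
    shift: float,
    seed: int,
    name: str = "rare",
    n_program_genes: int = 40,
    nb_dispersion: float = 10.0,
) -> CountMatrix:
    """Replace a random cell subset with draws from a new shifted population.

    The chosen cells keep their barcodes, depth and library labels but their
    counts are redrawn from a profile whose ``n_program_genes`` random genes
    are shifted by ``exp(shift * z)``; their truth label becomes ``name``.
    Requires an expected population of at least 5 cells.
    """
    n = matrix.n_cells
    n_rare = int(round(frequency * n))
    if n_rare < 5:
        raise SatkitError(
            f"frequency {frequency} of {n} cells gives {n_rare} < 5 rare cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_rare, replace=False)
    counts = sp.csc_matrix(matrix.counts).toarray()

    base_profile = counts.mean(axis=1) + 1e-9
    # shift only non-technical genes so the rare population passes QC
    tech = np.array(
        [g.startswith(("mt-", "Rps", "Rpl")) for g in matrix.gene_names], dtype=bool
    )
    eligible = np.where(~tech)[0]
    prog = rng.choice(eligible, size=min(n_program_genes, eligible.size), replace=False)
    factor = np.ones(matrix.n_genes)
    factor[prog] = np.exp(shift * rng.standard_normal(prog.size))
    profile = base_profile * factor
    profile /= profile.sum()

    truth = list(matrix.truth_labels) if matrix.truth_labels else ["unlabeled"] * n
    for i in chosen:
        depth = counts[:, i].sum()
        counts[:, i] = _nb_draw(rng, profile * depth, nb_dispersion)
        truth[i] = name
    return CountMatrix(
        counts=sp.csc_matrix(counts),
        gene_names=list(matrix.gene_names),
        barcodes=list(matrix.barcodes),
        library_labels=list(matrix.library_labels),
        truth_labels=truth,
    )
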