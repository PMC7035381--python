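"""Synthetic single-cell count matrices with known ground truth.

Generators for the competing explanations of rarely observed genes and for
the calibration inputs:

* *intermittent* genes (case B): every cell can express the gene; it is
  active with probability p and then carries about alpha transcripts,
  otherwise zero. Genes may share an activation *program* (the same
  per-cell on/off draw), which induces positive gene-gene correlations.
* *differentiated* populations (case A): disjoint cell types, each rare
  gene expressed continuously but only in cells of its own type; genes of
  different types are never co-expressed, the K = -1 signature.
* *telegraph* genes: counts from the exact two-state stationary law.
* *spike-ins*: ERCC-style sequences present in every cell at a fixed
  concentration, with optional multiplicative technical noise.

Every generator takes a seed, records it in the output, and returns the
ground truth alongside the matrix so downstream estimators can be scored.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import make_count_matrix
from .telegraph import TelegraphParams, sample_stationary


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IntermittentGeneSpec:
    """One intermittently transcribed gene.

    ``tissue_p`` overrides the activation probability per tissue (the peak
    level alpha is shared across tissues — the persistence hypothesis).
    Genes with the same ``program`` label share their per-cell activation
    draws, i.e. switch on and off together.
    """

    gene_id: str
    p_true: float
    alpha_true: float
    tissue_p: Mapping[str, float] | None = None
    program: str | None = None

    def __post_init__(self):
        if not 0 < self.p_true <= 1:
            raise ValueError(f"{self.gene_id}: p_true must be in (0, 1]")
        if self.alpha_true <= 0:
            raise ValueError(f"{self.gene_id}: alpha_true must be positive")
        for t, p in (self.tissue_p or {}).items():
            if not 0 < p <= 1:
                raise ValueError(f"{self.gene_id}: override p for {t} must be in (0, 1]")

    def p_in(self, tissue: str) -> float:
        if self.tissue_p and tissue in self.tissue_p:
            return self.tissue_p[tissue]
        return self.p_true


@dataclasses.dataclass
class DifferentiationSpec:
    """Disjoint cell types, each continuously expressing exclusive genes."""

    type_frequencies: Mapping[str, float]
    gene_assignments: Mapping[str, str]     # gene -> its one cell type
    active_level: Mapping[str, float]       # gene -> mean count when expressed

    def __post_init__(self):
        total = sum(self.type_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type frequencies sum to {total}, not 1")
        for g, t in self.gene_assignments.items():
            if t not in self.type_frequencies:
                raise ValueError(f"gene {g} assigned to unknown type {t}")
            if self.active_level.get(g, 0) <= 0:
                raise ValueError(f"gene {g} needs a positive active level")


@dataclasses.dataclass
class Spikein:
    """One exogenous sequence, same concentration in every cell."""

    sequence_id: str
    concentration: float          # amol/ul
    capture_efficiency: float = 1.0
    noise_scale: float = 0.0      # lognormal sigma of multiplicative noise

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.capture_efficiency <= 0:
            raise ValueError("capture efficiency must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_intermittent_counts(
    specs: Sequence[IntermittentGeneSpec],
    n_cells: int | Mapping[str, int],
    cell_size_dispersion: float = 0.0,
    seed: int = 0,
    mode: str = "poisson",
):
    """Counts under temporal intermittency (case B).

    Each cell activates each gene independently with the gene's (possibly
    tissue-specific) probability; genes sharing a ``program`` use the same
    draw. Active counts are Poisson with mean alpha (``mode="poisson"``)
    or exactly round(alpha) (``mode="fixed"``, the two-point schematic
    under which the moment-ratio estimators are exact); inactive counts
    are zero. ``cell_size_dispersion`` is the lognormal sigma of a
    per-cell scale multiplying alpha, emulating real cells' wide range of
    total counts.

    Returns ``(adata, truth)`` where ``truth`` has one row per
    (gene, tissue) with the generating p and alpha.
    """
    if not specs:
        raise ValueError("need at least one gene spec")
    if mode not in ("poisson", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(n_cells, int):
        n_cells = {"tissue0": n_cells}
    if not n_cells or any(n <= 0 for n in n_cells.values()):
        raise ValueError("n_cells must be positive for every tissue")
    if cell_size_dispersion < 0:
        raise ValueError("cell_size_dispersion must be non-negative")

    rng = np.random.default_rng(seed)
    programs = []
    prog_index = {}
    for s in specs:
        key = s.program if s.program is not None else f"__solo_{s.gene_id}"
        if key not in prog_index:
            prog_index[key] = len(programs)
            programs.append(key)
        # duplicate gene ids would silently collide downstream
    if len({s.gene_id for s in specs}) != len(specs):
        raise ValueError("duplicate gene ids")

    blocks, tissues_per_cell, cell_ids, truth = [], [], [], []
    for tissue, n in n_cells.items():
        scale = (
            np.exp(rng.normal(0.0, cell_size_dispersion, size=n))
            if cell_size_dispersion > 0 else np.ones(n)
        )
        u = rng.random((n, len(programs)))
        cols = []
        for s in specs:
            p = s.p_in(tissue)
            active = u[:, prog_index[s.program if s.program is not None
                                     else f"__solo_{s.gene_id}"]] < p
            lam = s.alpha_true * scale
            if mode == "poisson":
                counts = np.where(active, rng.poisson(lam), 0)
            else:
                counts = np.where(active, np.rint(lam).astype(np.int64), 0)
            cols.append(counts)
            truth.append((s.gene_id, tissue, p, s.alpha_true, s.program))
        blocks.append(np.column_stack(cols))
        tissues_per_cell += [tissue] * n
        cell_ids += [f"{tissue}_c{j}" for j in range(n)]

    X = sp.csr_matrix(np.vstack(blocks))
    adata = make_count_matrix(
        X, gene_ids=[s.gene_id for s in specs], cell_ids=cell_ids,
        tissues=tissues_per_cell, seed=seed,
    )
    truth_df = pd.DataFrame(
        truth, columns=["gene", "tissue", "p_true", "alpha_true", "program"]
    )
    return adata, truth_df


def gen_differentiated_counts(
    spec: DifferentiationSpec,
    n_cells: int,
    seed: int = 0,
    mode: str = "poisson",
):
    """Counts under cellular differentiation (case A).

    Each cell is assigned one type by the stated frequencies; a gene has
    nonzero counts only in cells of its own type (its supports are
    disjoint from those of genes of other types, making K = -1 exact for
    such pairs). Returns ``(adata, truth)`` with per-cell type labels and
    the gene -> type map.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if mode not in ("poisson", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    types = list(spec.type_frequencies)
    freqs = np.array([spec.type_frequencies[t] for t in types], dtype=float)
    cell_type = rng.choice(len(types), size=n_cells, p=freqs / freqs.sum())

    genes = list(spec.gene_assignments)
    cols = []
    for g in genes:
        own = cell_type == types.index(spec.gene_assignments[g])
        level = spec.active_level[g]
        if mode == "poisson":
            counts = np.where(own, rng.poisson(level, size=n_cells), 0)
        else:
            counts = np.where(own, int(round(level)), 0)
        cols.append(counts)

    adata = make_count_matrix(
        sp.csr_matrix(np.column_stack(cols)),
        gene_ids=genes,
        cell_ids=[f"c{j}" for j in range(n_cells)],
        tissues=["tissue0"] * n_cells,
        seed=seed,
    )
    adata.obs["cell_type"] = pd.Categorical([types[t] for t in cell_type])
    truth_df = pd.DataFrame({
        "gene": genes,
        "cell_type": [spec.gene_assignments[g] for g in genes],
        "active_level": [spec.active_level[g] for g in genes],
    })
    return adata, truth_df


def gen_telegraph_counts(
    params: Sequence[TelegraphParams],
    n_cells: int,
    seed: int = 0,
):
    """Independent genes, each with counts from the exact telegraph
    stationary law (Poisson-Beta). Returns ``(adata, truth)`` with the
    rates and derived (p0, M0) per gene."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    cols = [sample_stationary(par, n_cells, rng) for par in params]
    genes = [f"tele{g:04d}" for g in range(len(params))]
    adata = make_count_matrix(
        sp.csr_matrix(np.column_stack(cols)),
        gene_ids=genes,
        cell_ids=[f"c{j}" for j in range(n_cells)],
        tissues=["tissue0"] * n_cells,
        seed=seed,
    )
    truth_df = pd.DataFrame({
        "gene": genes,
        "k_on": [p.k_on for p in params],
        "k_off": [p.k_off for p in params],
        "k_tr": [p.k_tr for p in params],
        "k_deg": [p.k_deg for p in params],
        "p0": [p.p0 for p in params],
        "M0": [p.M0 for p in params],
    })
    return adata, truth_df


def gen_spikein_counts(
    panel: Sequence[Spikein],
    n_cells: int,
    cell_scale_variation: float = 0.0,
    seed: int = 0,
    tissue: str = "tissue0",
):
    """Spike-in counts: every sequence in every cell.

    Expected count = concentration x capture efficiency x per-cell scale
    (lognormal with sigma ``cell_scale_variation``), perturbed by each
    sequence's multiplicative lognormal noise, then rounded. With zero
    noise and zero scale variation the counts are identical across cells
    and the estimated intermittency is exactly zero.
    """
    if not panel:
        raise ValueError("empty spike-in panel")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if cell_scale_variation < 0:
        raise ValueError("cell_scale_variation must be non-negative")
    rng = np.random.default_rng(seed)
    scale = (
        np.exp(rng.normal(0.0, cell_scale_variation, size=n_cells))
        if cell_scale_variation > 0 else np.ones(n_cells)
    )
    cols = []
    for s in panel:
        expected = s.concentration * s.capture_efficiency * scale
        if s.noise_scale > 0:
            expected = expected * np.exp(rng.normal(0.0, s.noise_scale, size=n_cells))
        cols.append(np.rint(expected).astype(np.int64))
    adata = make_count_matrix(
        sp.csr_matrix(np.column_stack(cols)),
        gene_ids=[s.sequence_id for s in panel],
        cell_ids=[f"{tissue}_c{j}" for j in range(n_cells)],
        tissues=[tissue] * n_cells,
        is_spikein=[True] * len(panel),
        concentration=[s.concentration for s in panel],
        seed=seed,
    )
    truth_df = pd.DataFrame({
        "sequence": [s.sequence_id for s in panel],
        "concentration": [s.concentration for s in panel],
        "capture_efficiency": [s.capture_efficiency for s in panel],
        "noise_scale": [s.noise_scale for s in panel],
    })
    return adata, truth_df


# ---------------------------------------------------------------------------
# convenience builders
# ---------------------------------------------------------------------------

def random_intermittent_specs(
    n_genes: int,
    tissues: Sequence[str],
    seed: int = 0,
    alpha_exponent: float = 2.35,
    alpha_min: float = 20.0,
    p_low: float = 0.01,
    p_high: float = 0.5,
    n_programs: int = 0,
) -> list[IntermittentGeneSpec]:
    """Gene specs emulating the persistence structure of real tissues.

    Peak levels alpha are shared across tissues and drawn from a power-law
    tail P(alpha) ~ alpha^-alpha_exponent above ``alpha_min``; activation
    probabilities are drawn log-uniformly in [p_low, p_high] independently
    per tissue (activity persists, intermittency varies). With
    ``n_programs > 0`` genes are cycled through that many shared
    activation programs.
    """
    rng = np.random.default_rng(seed)
    alphas = alpha_min * (1.0 - rng.random(n_genes)) ** (-1.0 / (alpha_exponent - 1.0))
    specs = []
    for g in range(n_genes):
        tissue_p = {
            t: float(np.exp(rng.uniform(np.log(p_low), np.log(p_high))))
            for t in tissues
        }
        specs.append(IntermittentGeneSpec(
            gene_id=f"gene{g:05d}",
            p_true=tissue_p[tissues[0]],
            alpha_true=float(alphas[g]),
            tissue_p=tissue_p,
            program=f"prog{g % n_programs}" if n_programs else None,
        ))
    return specs


def ercc_panel(
    n: int = 96,
    seed: int = 0,
    conc_low: float = 0.1,
    conc_high: float = 5000.0,
    capture_efficiency: float = 0.05,
    noise_scale: float = 0.0,
) -> list[Spikein]:
    """An ERCC-style panel: log-uniform concentrations in amol/ul."""
    rng = np.random.default_rng(seed)
    conc = np.exp(rng.uniform(np.log(conc_low), np.log(conc_high), size=n))
    return [
        Spikein(
            sequence_id=f"ERCC-{i:05d}",
            concentration=float(c),
            capture_efficiency=capture_efficiency,
            noise_scale=noise_scale,
        )
        for i, c in enumerate(np.sort(conc), start=1)
    ]
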