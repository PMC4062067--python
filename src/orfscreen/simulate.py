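"""Stochastic simulation of a pooled ORF-overexpression resistance screen.

The generative model follows the biology of a gain-of-function screen in
cultured cells:

1. An annotated ORF library (thousands of clones, partitioned into minipools
   during cloning) is integrated into cells by lentivirus at low multiplicity
   of infection, so integration counts per cell are Poisson.
2. The sorted, integrated population is bottlenecked to a fixed number of
   cells; per-ORF representation is multinomial with a size-dependent bias
   (smaller inserts clone and package more efficiently, so sampling weight
   scales as ``length ** -beta``).
3. Under drug, cells grow as a discrete branching process: each generation a
   cell survives with probability ``min(1, (1 - drug_kill_prob) * effect)``
   and then divides. Vehicle (DMSO) control populations grow unselected.
   A carrying capacity models flask saturation by multinomial downsampling.
4. The surviving pool is read out either on a two-channel array (intensity
   proportional to abundance, with cross-hybridization bleed between
   homologous ORFs, multiplicative log-normal noise and a detection floor)
   or by sequencing (per-base read coverage along each ORF).

Everything is reproducible: a master seed expands into per-stage child
streams via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import OrfMismatchError, ParameterError

__all__ = [
    "AbundanceState",
    "SimConfig",
    "make_library",
    "simulate_initial_representation",
    "simulate_infection",
    "simulate_selection",
    "simulate_array_readout",
    "simulate_read_coverage",
    "simulate_screen",
    "methotrexate_like_scenario",
    "crosshyb_bleed_matrix",
    "child_seeds",
]

#: Shortest ORF the library generator will emit, in nucleotides.
MIN_ORF_LENGTH = 75

LIBRARY_COLUMNS = ["orf_id", "gene_symbol", "length_nt", "pool_id", "mappable"]


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Expand a master seed into ``n`` independent child seed sequences.

    The derivation is the documented one used by every pipeline stage:
    ``numpy.random.SeedSequence(seed).spawn(n)``, so a stage can be re-run in
    isolation and reproduce exactly what the full pipeline produced.
    """
    return np.random.SeedSequence(seed).spawn(n)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AbundanceState:
    """Per-ORF cell (or genome-copy) counts at one time point of the screen.

    ``counts`` is aligned to the library row order. ``label`` records the
    stage: ``T0`` (post-sort bottleneck), ``post_infection`` or
    ``post_selection``.
    """

    counts: np.ndarray
    generation: int = 0
    label: str = "T0"

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise ParameterError("counts must be a 1-D integer vector")
        if (counts < 0).any():
            raise ParameterError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SimConfig:
    """Parameters of the screen simulation.

    Attributes
    ----------
    seed
        Master seed; all stage randomness derives from it.
    moi
        Mean lentiviral integrations per cell (Poisson rate). Default 0.3.
    size_bias_exponent
        β ≥ 0; initial sampling weight of an ORF is ``length ** -beta``.
    n_doublings
        Selection length in cell generations (screens run ~20-30 doublings).
    drug_kill_prob
        Per-generation kill probability for a drug-sensitive cell.
    resistance_effects
        Per-ORF survival multiplier ≥ 1 (array aligned to the library, or a
        mapping from row index to effect). Effect 1 is fully sensitive;
        effect ``1/(1-drug_kill_prob)`` or larger is fully resistant.
    noise_sigma
        SD of the additive Gaussian noise on log2 readout intensity.
    intensity_floor
        Detection floor of the array scanner on the raw intensity scale.
    crosshyb
        Optional (n, n) matrix H with H[i, j] = fraction of ORF j signal
        bleeding into probe i; diagonal 1. ``None`` means identity.
    carrying_capacity
        Maximum simulated population size; enforced by multinomial
        downsampling each generation, preserving relative frequencies.
    """

    seed: int = 0
    moi: float = 0.3
    size_bias_exponent: float = 1.0
    n_doublings: int = 25
    drug_kill_prob: float = 0.6
    resistance_effects: np.ndarray | Mapping[int, float] | None = None
    noise_sigma: float = 0.5
    intensity_floor: float = 1.0
    crosshyb: np.ndarray | sparse.spmatrix | None = None
    carrying_capacity: int = 100_000_000

    def validate(self) -> None:
        if self.moi < 0:
            raise ParameterError("moi must be >= 0")
        if self.size_bias_exponent < 0:
            raise ParameterError("size_bias_exponent must be >= 0")
        if self.n_doublings < 0:
            raise ParameterError("n_doublings must be >= 0")
        if not 0.0 <= self.drug_kill_prob <= 1.0:
            raise ParameterError("drug_kill_prob must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.intensity_floor <= 0:
            raise ParameterError("intensity_floor must be > 0")
        if self.carrying_capacity < 1:
            raise ParameterError("carrying_capacity must be >= 1")
        if self.crosshyb is not None:
            H = self.crosshyb
            data = H.data if sparse.issparse(H) else np.asarray(H)
            if data.size and ((data < 0).sum() or (data > 1).sum()):
                raise ParameterError("crosshyb entries must lie in [0, 1]")

    def effects_vector(self, n_orfs: int) -> np.ndarray:
        """Materialize ``resistance_effects`` as a dense length-n vector."""
        eff = np.ones(n_orfs, dtype=float)
        if self.resistance_effects is None:
            return eff
        if isinstance(self.resistance_effects, Mapping):
            for i, e in self.resistance_effects.items():
                eff[int(i)] = float(e)
        else:
            arr = np.asarray(self.resistance_effects, dtype=float)
            if arr.shape != (n_orfs,):
                raise ParameterError(
                    f"resistance_effects length {arr.shape} does not match "
                    f"library size {n_orfs}"
                )
            eff = arr.copy()
        if (eff < 1).any():
            raise ParameterError("resistance effects must be >= 1")
        return eff


def _default_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal ORF lengths, clipped to the plausible 200-6,000 nt range.

    Median ~1.1 kb matches a typical full-length human ORF collection.
    """
    lengths = rng.lognormal(mean=np.log(1100.0), sigma=0.65, size=n)
    return np.clip(np.round(lengths), 200, 6000).astype(np.int64)


def make_library(
    n_orfs: int,
    pool_size: int = 376,
    length_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate an annotated synthetic ORF library.

    Pools are filled in order, so ``ceil(n_orfs / pool_size)`` pools exist and
    only the last one may be partial. Returns a DataFrame with columns
    ``orf_id, gene_symbol, length_nt, pool_id, mappable``.
    """
    if n_orfs < 1:
        raise ParameterError("n_orfs must be >= 1")
    if pool_size < 1:
        raise ParameterError("pool_size must be >= 1")
    rng = _rng(seed)
    draw = length_distribution or _default_lengths
    lengths = np.asarray(draw(rng, n_orfs), dtype=np.int64)
    if (lengths < MIN_ORF_LENGTH).any():
        raise ParameterError(f"ORF lengths must be >= {MIN_ORF_LENGTH} nt")
    idx = np.arange(n_orfs)
    return pd.DataFrame(
        {
            "orf_id": [f"ORF{i + 1:05d}" for i in idx],
            "gene_symbol": [f"GENE{i + 1:05d}" for i in idx],
            "length_nt": lengths,
            "pool_id": idx // pool_size + 1,
            "mappable": True,
        }
    )


def n_pools(library: pd.DataFrame) -> int:
    return int(library["pool_id"].max())


def simulate_initial_representation(
    library: pd.DataFrame,
    total_cells: int,
    beta: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> AbundanceState:
    """Bottleneck the library into ``total_cells`` cells.

    Counts are multinomial with probability ``p_i ∝ length_i ** -beta``;
    beta > 0 over-represents short clones, matching the size-dependent
    abundance seen when an ORFeome is sequenced out of cells.
    """
    if total_cells < 0:
        raise ParameterError("total_cells must be >= 0")
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    rng = _rng(seed)
    lengths = library["length_nt"].to_numpy(dtype=float)
    weights = lengths ** -float(beta)
    counts = rng.multinomial(int(total_cells), weights / weights.sum())
    return AbundanceState(counts=counts, generation=0, label="T0")


def simulate_infection(
    n_cells: int,
    moi: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Draw per-cell lentiviral integration counts at the given MOI.

    Returns ``(counts, infected_fraction)`` where counts ~ Poisson(moi) and
    the fraction is the observed share of cells with at least one
    integration (expectation ``1 - exp(-moi)``).
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    if moi < 0:
        raise ParameterError("moi must be >= 0")
    rng = _rng(seed)
    counts = rng.poisson(moi, size=int(n_cells))
    frac = float((counts > 0).mean()) if n_cells else 0.0
    return counts, frac


def simulate_selection(
    state: AbundanceState,
    cfg: SimConfig,
    drug_present: bool,
    seed: int | np.random.Generator | None = None,
) -> AbundanceState:
    """Grow the population for ``cfg.n_doublings`` survive-then-double
    generations.

    Under drug, a cell carrying ORF i survives a generation with probability
    ``s_i = min(1, (1 - drug_kill_prob) * effect_i)``; without drug s_i = 1
    and growth is deterministic doubling. The population is capped at
    ``cfg.carrying_capacity`` by multinomial downsampling, which preserves
    expected relative frequencies (a flask saturates; relative enrichment is
    what the readout measures).
    """
    cfg.validate()
    rng = _rng(cfg.seed if seed is None else seed)
    n = state.counts.size
    if drug_present:
        s = np.minimum(1.0, (1.0 - cfg.drug_kill_prob) * cfg.effects_vector(n))
    else:
        s = np.ones(n)
    counts = state.counts.copy()
    cap = int(cfg.carrying_capacity)
    for _ in range(cfg.n_doublings):
        survivors = np.where(s >= 1.0, counts, rng.binomial(counts, s))
        counts = 2 * survivors
        total = int(counts.sum())
        if total > cap:
            counts = rng.multinomial(cap, counts / total)
    return AbundanceState(
        counts=counts,
        generation=state.generation + cfg.n_doublings,
        label="post_selection",
    )


def _readout_channel(
    counts: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    raw = counts.astype(float)
    if cfg.crosshyb is not None:
        H = cfg.crosshyb
        raw = (H @ raw) if sparse.issparse(H) else np.asarray(H, dtype=float) @ raw
    if cfg.noise_sigma > 0:
        raw = raw * np.exp2(rng.normal(0.0, cfg.noise_sigma, size=raw.size))
    return np.maximum(cfg.intensity_floor, raw)


def simulate_array_readout(
    state_drug: AbundanceState,
    state_ctrl: AbundanceState,
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
    orf_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hybridize one paired drug/DMSO replicate onto the simulated array.

    Probe signal is ``max(floor, (H @ counts) * 2**eps)`` with
    ``eps ~ Normal(0, noise_sigma**2)`` drawn independently per probe and
    channel; both channels share the bleed matrix H and the floor. Returns a
    DataFrame with columns ``drug`` and ``dmso``.
    """
    cfg.validate()
    if state_drug.counts.size != state_ctrl.counts.size:
        raise OrfMismatchError("drug and control states index different libraries")
    rng = _rng(cfg.seed if seed is None else seed)
    out = pd.DataFrame(
        {
            "drug": _readout_channel(state_drug.counts, cfg, rng),
            "dmso": _readout_channel(state_ctrl.counts, cfg, rng),
        }
    )
    if orf_ids is not None:
        out.index = pd.Index(orf_ids, name="orf_id")
    return out


def simulate_read_coverage(
    state: AbundanceState,
    library: pd.DataFrame,
    n_reads: int,
    read_len: int = 50,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Simulate shotgun sequencing of the pooled inserts.

    Reads are allocated to ORFs by a multinomial with weight
    ``count_i * length_i`` (longer, more abundant templates yield more
    fragments), then placed uniformly; an ORF shorter than the read length is
    covered end to end by each of its reads. Depth intervals are 0-based,
    half-open. Returns ``{orf_id: per-base depth vector}``.
    """
    if n_reads < 0:
        raise ParameterError("n_reads must be >= 0")
    if read_len < 1:
        raise ParameterError("read_len must be >= 1")
    rng = _rng(seed)
    lengths = library["length_nt"].to_numpy(dtype=np.int64)
    if state.counts.size != lengths.size:
        raise OrfMismatchError("state and library sizes differ")
    weights = state.counts.astype(float) * lengths
    total = weights.sum()
    if total > 0 and n_reads > 0:
        reads_per_orf = rng.multinomial(int(n_reads), weights / total)
    else:
        reads_per_orf = np.zeros(lengths.size, dtype=np.int64)
    profiles: dict[str, np.ndarray] = {}
    for orf_id, length, r in zip(library["orf_id"], lengths, reads_per_orf):
        depth = np.zeros(length, dtype=np.int64)
        if r > 0:
            if length <= read_len:
                depth += int(r)
            else:
                starts = rng.integers(0, length - read_len + 1, size=int(r))
                diff = np.zeros(length + 1, dtype=np.int64)
                np.add.at(diff, starts, 1)
                np.add.at(diff, starts + read_len, -1)
                depth = np.cumsum(diff[:-1])
        profiles[str(orf_id)] = depth
    return profiles


def crosshyb_bleed_matrix(
    n_orfs: int,
    pairs: Sequence[tuple[int, int, float]],
) -> sparse.csr_matrix:
    """Build a bleed matrix H from ``(probe_i, source_j, weight)`` triples.

    H[i, j] = weight means a fraction ``weight`` of ORF j's signal appears on
    probe i (the mechanism behind near-identical paralogs scoring as false
    positives). The diagonal is 1.
    """
    H = sparse.lil_matrix((n_orfs, n_orfs))
    H.setdiag(1.0)
    for i, j, w in pairs:
        if not 0.0 <= w <= 1.0:
            raise ParameterError("bleed weights must lie in [0, 1]")
        H[int(i), int(j)] = w
    return H.tocsr()


def simulate_screen(
    library: pd.DataFrame,
    cfg: SimConfig,
    total_cells: int,
    n_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generative screen: bottleneck → paired selection → readout.

    Each replicate is an independent infection aliquot: its own T0 bottleneck
    and its own drug and DMSO cultures. Returns ``(intensities, samples)``
    where ``intensities`` has one column per sample (rows = ORFs) and
    ``samples`` is the sample sheet (sample_id, channel, replicate, pair_id).
    """
    cfg.validate()
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    seeds = child_seeds(cfg.seed, 3 * n_replicates)
    columns: dict[str, np.ndarray] = {}
    rows = []
    for rep in range(1, n_replicates + 1):
        s_t0, s_sel, s_read = seeds[3 * (rep - 1): 3 * rep]
        t0 = simulate_initial_representation(
            library, total_cells, cfg.size_bias_exponent, np.random.default_rng(s_t0)
        )
        rng_sel = np.random.default_rng(s_sel)
        drug = simulate_selection(t0, cfg, drug_present=True, seed=rng_sel)
        ctrl = simulate_selection(t0, cfg, drug_present=False, seed=rng_sel)
        readout = simulate_array_readout(
            drug, ctrl, cfg, seed=np.random.default_rng(s_read),
            orf_ids=library["orf_id"],
        )
        pair = f"pair{rep}"
        for channel in ("drug", "dmso"):
            sample_id = f"{channel}_rep{rep}"
            columns[sample_id] = readout[channel].to_numpy()
            rows.append(
                {"sample_id": sample_id, "channel": channel,
                 "replicate": rep, "pair_id": pair}
            )
    intensities = pd.DataFrame(columns, index=pd.Index(library["orf_id"], name="orf_id"))
    samples = pd.DataFrame(rows)
    return intensities, samples


def methotrexate_like_scenario(
    seed: int = 0,
    n_orfs: int = 376,
    cells_per_orf: int = 41,
    resistant_index: int = 0,
    bleed_pairs: Sequence[tuple[int, int, float]] | None = None,
    **cfg_overrides,
) -> tuple[pd.DataFrame, SimConfig, int]:
    """Bundled single-pool scenario: one fully resistant ORF among ``n_orfs``.

    Mirrors the proof-of-concept pool in which the drug's known target is the
    single clone whose overexpression rescues the drug: the planted ORF gets
    a survival multiplier that cancels the kill probability, every other
    clone decays. ORFs joined by a bleed pair are assigned identical,
    library-median lengths: cross-hybridizing paralogs are near-identical in
    sequence, so they neither gain nor lose representation relative to each
    other through the size bias. Returns ``(library, config, total_cells)``.
    """
    lib_seed, _ = child_seeds(seed, 2)
    library = make_library(n_orfs, pool_size=n_orfs, seed=np.random.default_rng(lib_seed))
    if bleed_pairs:
        median_len = int(library["length_nt"].median())
        for i, j, _ in bleed_pairs:
            library.loc[[int(i), int(j)], "length_nt"] = median_len
    kill = float(cfg_overrides.pop("drug_kill_prob", 0.6))
    effects = {int(resistant_index): 1.0 / (1.0 - kill)}
    crosshyb = (
        crosshyb_bleed_matrix(n_orfs, bleed_pairs) if bleed_pairs else None
    )
    cfg = SimConfig(
        seed=seed,
        drug_kill_prob=kill,
        resistance_effects=effects,
        crosshyb=crosshyb,
        carrying_capacity=cfg_overrides.pop("carrying_capacity", 1_000_000),
        **cfg_overrides,
    )
    return library, cfg, cells_per_orf * n_orfs
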