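"""Synthetic genomes, chromatin, expression and sequence with planted,
parameterised effects, so every downstream stage of the pipeline can be
scored against a known ground truth.

The generator emulates a ZW system: several autosomes, a Z chromosome
whose differentiated stratum ("S0") is hemizygous in females plus a
still-recombining pseudoautosomal region, and a gene-free W.  Seven
histone marks are emitted per 200-bp bin from a hidden chromatin-state
Markov chain (Poisson counts, high rate when the state's Bernoulli mark
draw is on).  Expression follows each gene's chromatin class; a
configurable fraction of gonadal genes is sex-biased, a configurable
fraction of those carries sex-discordant chromatin; S0 genes are dosage
compensated (equal expected female and male TPM) while the female S0
H4K16ac signal is boosted by a configurable factor and peak-shaped signal
blocks are planted over a fraction of expressed S0 genes.  An AT-rich
motif is planted densely inside S0 peaks and sparsely elsewhere.

Every dataset is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    BinnedTrack,
    GeneAnnotation,
    GenomeModel,
    Interval,
    SampleKey,
)
from .signatures import CATEGORIES, MARK_ROLES, signature_of

MARKS = tuple(MARK_ROLES)
SEXES = ("female", "male")
TISSUES = ("head", "gonad")


def default_emission_matrix() -> np.ndarray:
    """Emission probabilities for the default 12-state truth.

    Four active-dominated states, one polycomb, two heterochromatin, two
    mixed states, two weak sub-threshold states and one null state; all
    twelve emission patterns are pairwise distinct so that state matching
    by emission correlation is well defined.
    """
    off = 0.04
    idx = {m: i for i, m in enumerate(MARKS)}
    # Per-mark amplitudes are budgeted (column sums <= ~2.0) so that no
    # mark's genome-wide mean count saturates the Poisson binarization
    # threshold; high-occupancy marks at high amplitude would push the
    # present/absent threshold up and clip their own recovery.
    patterns = [
        {"H3K27ac": 0.80, "H3K4me3": 0.70, "H4K16ac": 0.70},     # promoter
        {"H4K16ac": 0.75, "H3K36me3": 0.70},                     # elongation
        {"H3K27ac": 0.70, "H3K4me3": 0.70, "H4K16ac": 0.70,
         "H3K36me3": 0.70},                                      # strong active
        {"H3K4me3": 0.70, "H4K16ac": 0.65},                      # weak promoter
        {"H3K27me3": 0.80},                                      # polycomb
        {"H3K9me2": 0.75, "H3K9me3": 0.75},                      # heterochromatin
        {"H3K9me3": 0.80},                                       # H3K9me3-only
        {"H3K27ac": 0.75, "H3K27me3": 0.70},                     # mixed A+P
        {"H3K36me3": 0.75, "H3K9me2": 0.70},                     # mixed A+H
        {"H3K27me3": 0.45, "H3K9me2": 0.45},                     # weak repressive
        {"H3K4me3": 0.18, "H3K9me3": 0.25},                      # weak transitional
        {},                                                      # null
    ]
    E = np.full((len(patterns), len(MARKS)), off)
    # the null state keeps a fixed low-amplitude pattern so its emission
    # vector is never exactly constant (correlation matching needs variance)
    E[-1] = [0.02, 0.04, 0.03, 0.02, 0.04, 0.03, 0.02]
    for k, pat in enumerate(patterns[:-1]):
        for m, p in pat.items():
            E[k, idx[m]] = p
    return E


def well_separated_emissions(n_states: int, p_on: float = 0.9, p_off: float = 0.05) -> np.ndarray:
    """Small planted-truth helper: distinct mark subsets per state."""
    subsets = [
        (0, 1), (2, 3), (4,), (5, 6), (0, 4), (1, 5), (2, 6), (0, 1, 2, 3),
        (3, 4), (1, 6),
    ]
    if n_states > len(subsets) + 1:
        raise ValueError("too many states for the preset subsets")
    E = np.full((n_states, len(MARKS)), p_off)
    for k in range(n_states - 1):
        for i in subsets[k]:
            E[k, i] = p_on
    E[n_states - 1] = [0.02, 0.04, 0.03, 0.02, 0.04, 0.03, 0.02]
    return E


def recovery_truth() -> tuple[np.ndarray, tuple[float, ...]]:
    """Five-state planted truth for scoring state recovery end to end.

    Two high-occupancy "shades" of the same active profile (differing by
    one extra mark) plus three distinct lower-occupancy profiles.  The
    amplitudes keep every mark's genome-wide mean count low enough that
    Poisson binarization at the default tail probability stays close to
    lossless (high rates saturate the threshold and bias the recovered
    emissions down); the two shades give the state-number selection curve
    a sharp plateau onset at K = 5, because any four-state model must
    collapse them while they also dominate genome occupancy.
    """
    p_off = 0.02
    E = np.full((5, len(MARKS)), p_off)
    E[0, [0, 1]] = 0.28              # base shade
    E[1, [0, 1]] = 0.28              # second shade: base + two extra marks
    E[1, [2, 6]] = 0.35
    E[2, 3] = 0.85                   # sharp single-mark profiles
    E[3, 4] = 0.85
    E[4, 5] = 0.85
    weights = (0.31, 0.31, 0.127, 0.127, 0.126)
    return E, weights


def recovery_config(seed: int = 1, **overrides) -> "SimulationConfig":
    """Chromatin-only config with the five-state recovery truth planted
    (no genes, longer segments); the standard bench for scoring
    binarization, emission recovery, segmentation and state-number
    selection."""
    E, w = recovery_truth()
    defaults = dict(
        seed=seed,
        emission_matrix=E,
        stationary_weights=w,
        self_transition=0.97,
        autosome_length=2_000_000,  # 10k bins per chromosome
        z_length=2_000_000,
        lambda_bg=0.5,
        lambda_on=20.0,
        genes_per_autosome=0,
        n_s0_genes=0,
        n_intergenic_tes=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_autosomes: int = 5
    autosome_length: int = 4_000_000
    z_length: int = 4_000_000
    s0_fraction: float = 0.5
    w_length: int = 300_000
    bin_size: int = 200
    # genes and TEs
    genes_per_autosome: int = 1000
    n_s0_genes: int = 139
    gene_length_range: tuple[int, int] = (1200, 1800)
    min_intergenic_gap: int = 600
    te_intron_fraction: float = 0.3
    te_exon_fraction: float = 0.02
    n_intergenic_tes: int = 200
    # chromatin
    emission_matrix: np.ndarray | None = None  # default 12-state preset
    stationary_weights: tuple | None = None  # None = preset / uniform
    self_transition: float = 0.95
    lambda_bg: float = 0.2
    lambda_on: float = 20.0
    replicates: int = 2
    extra_replicate_marks: tuple[str, ...] = ("H3K27me3",)  # 3 replicates
    # expression
    class_log2_tpm: dict = field(
        default_factory=lambda: {
            "active": 6.0,
            "mixed": 3.5,
            "repressive": 1.0,
            "null": -2.0,
        }
    )
    gene_log2_sd: float = 1.0
    replicate_log2_sd: float = 0.15
    gene_active_fraction: float = 0.65  # genes whose body is forced active
    sex_biased_fraction: float = 0.10  # of (pseudo)autosomal genes, gonads
    sex_bias_log2fc: float = 2.0  # 4-fold
    discordant_fraction_biased: float = 0.40
    discordant_fraction_unbiased: float = 0.05
    # dosage compensation
    h4k16ac_boost: float = 2.0  # female S0 only
    s0_peak_gene_fraction: float = 84 / 139
    autosome_peak_gene_fraction: float = 0.03
    peak_width: int = 1000
    peak_log2_expr_bonus: float = 1.0
    # motif
    motif: str = "TTATTTAT"
    motif_background_per_mb: float = 60.0
    motif_s0_factor: float = 1.0
    motif_peak_base_fraction: float = 0.06

    def __post_init__(self) -> None:
        if not self.lambda_on > self.lambda_bg > 0:
            raise ValueError("require lambda_on > lambda_bg > 0")
        if self.h4k16ac_boost <= 0:
            raise ValueError("boost must be positive")
        E = self.emissions()
        if np.any((E < 0) | (E > 1)):
            raise ValueError("emission probabilities must lie in [0, 1]")

    def emissions(self) -> np.ndarray:
        if self.emission_matrix is None:
            return default_emission_matrix()
        return np.asarray(self.emission_matrix, dtype=float)

    @property
    def n_states(self) -> int:
        return self.emissions().shape[0]

    def transition_matrix(self) -> np.ndarray:
        """Sticky chain: leave with prob (1 - self_transition), re-enter
        proportionally to the stationary weights (uniform by default), so
        the stationary distribution equals the configured weights."""
        K = self.n_states
        if K == 1:
            return np.ones((1, 1))
        if self.stationary_weights is None:
            if self.emission_matrix is None:
                # repressive/null-heavy intergenic occupancy for the
                # 12-state preset (repeat-rich genome); active states get
                # most of their mass from the gene-body overwrite
                w = np.array(
                    [0.012, 0.012, 0.012, 0.012, 0.10, 0.13, 0.10,
                     0.06, 0.06, 0.11, 0.11, 0.292]
                )
            else:
                w = np.full(K, 1.0 / K)
        else:
            w = np.asarray(self.stationary_weights, dtype=float)
            if len(w) != K or np.any(w <= 0):
                raise ValueError("stationary_weights must be positive, one per state")
            w = w / w.sum()
        s = self.self_transition
        A = s * np.eye(K) + (1 - s) * np.tile(w, (K, 1))
        return A

    def n_replicates(self, mark: str) -> int:
        return self.replicates + (1 if mark in self.extra_replicate_marks else 0)


@dataclass
class GroundTruth:
    """Everything needed to score the downstream stages."""

    emissions: np.ndarray
    transitions: np.ndarray
    state_paths: dict  # (sex, tissue) -> {chrom: int array}
    mark_masks: dict  # (mark, sex, tissue, rep) -> {chrom: bool array}
    gene_table: pd.DataFrame  # per-gene truth
    peak_intervals: list[Interval]
    s0_peak_gene_ids: list[str]
    motif_positions: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeModel
    genes: list[GeneAnnotation]
    tes: list[Interval]
    tracks: dict  # (mark, sex, tissue, rep) -> BinnedTrack
    tpm: pd.DataFrame
    truth: GroundTruth
    sequences: dict | None = None


# ---------------------------------------------------------------- genome


def _place_genes(
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    prefix: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[GeneAnnotation]:
    lmin, lmax = cfg.gene_length_range
    min_gap = cfg.min_intergenic_gap
    lengths = rng.integers(lmin, lmax + 1, size=n)
    space = hi - lo
    slack = space - int(lengths.sum())
    if slack < n * min_gap:
        raise ValueError(
            f"{n} genes do not fit in {chrom}:{lo}-{hi} "
            f"(need {lengths.sum() + n * min_gap} bp, have {space})"
        )
    gaps = rng.multinomial(
        slack - n * min_gap, np.full(n + 1, 1 / (n + 1))
    ) + np.r_[np.full(n, min_gap, dtype=int), 0]
    out = []
    pos = int(lo)
    for i in range(n):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            GeneAnnotation(
                gene_id=f"{prefix}{i + 1:04d}",
                body=Interval(chrom, start, end, strand),
            )
        )
        pos = end
    return out


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeModel, list[GeneAnnotation], list[Interval]]:
    """Genome model, gene annotation and TE annotation.

    The S0 region holds exactly ``n_s0_genes`` genes; PAR genes are placed
    at autosomal density.  TE flags are derived from the placed TE
    intervals (interior of the body = intron; the outer 100 bp at each
    end stand in for exonic sequence).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms = [(f"chr{i + 1}", config.autosome_length) for i in range(config.n_autosomes)]
    chroms += [("chrZ", config.z_length), ("chrW", config.w_length)]
    s0_len = int(config.z_length * config.s0_fraction)
    regions = [
        (Interval("chrZ", 0, s0_len), "S0"),
        (Interval("chrZ", s0_len, config.z_length), "PAR"),
        (Interval("chrW", 0, config.w_length), "W"),
    ]
    genome = GenomeModel(chromosomes=chroms, regions=regions)

    genes: list[GeneAnnotation] = []
    for i in range(config.n_autosomes):
        chrom = f"chr{i + 1}"
        genes += _place_genes(
            chrom, 0, config.autosome_length, config.genes_per_autosome,
            f"{chrom}_g", config, rng,
        )
    genes += _place_genes("chrZ", 0, s0_len, config.n_s0_genes, "chrZ_s0_g", config, rng)
    n_par = round(
        config.genes_per_autosome * (config.z_length - s0_len) / config.autosome_length
    )
    genes += _place_genes("chrZ", s0_len, config.z_length, n_par, "chrZ_par_g", config, rng)

    tes: list[Interval] = []
    te_len = 150
    for g in genes:
        body = g.body
        interior_lo, interior_hi = body.start + 100, body.end - 100 - te_len
        r = rng.random()
        if r < config.te_exon_fraction:
            g.te_in_exon = True
            tes.append(Interval(body.chrom, body.start, body.start + te_len))
        elif r < config.te_exon_fraction + config.te_intron_fraction:
            if interior_hi > interior_lo:
                g.te_in_intron = True
                start = int(rng.integers(interior_lo, interior_hi))
                tes.append(Interval(body.chrom, start, start + te_len))
    # intergenic TEs (informational only; they set no gene flags)
    sizes = dict(genome.chromosomes)
    for _ in range(config.n_intergenic_tes):
        chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
        start = int(rng.integers(0, sizes[chrom] - te_len))
        iv = Interval(chrom, start, start + te_len)
        if not any(iv.overlaps(g.body) for g in genes if g.body.chrom == chrom):
            tes.append(iv)
    return genome, genes, tes


# ----------------------------------------------------------- gene truth


def _true_gene_classes(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation],
    state_paths: dict,
    catmap: dict[int, str],
) -> pd.DataFrame:
    """True signature and broad class per gene/tissue from the base paths."""
    bs = config.bin_size
    rows = []
    for g in genes:
        row = {"gene_id": g.gene_id, "region": genome.region_of_interval(g.body)}
        for tissue in TISSUES:
            path = state_paths[("female", tissue)][g.body.chrom]
            first, last = g.body.start // bs, min((g.body.end - 1) // bs, len(path) - 1)
            cats = {catmap[int(s) + 1] for s in np.unique(path[first : last + 1])}
            sig = signature_of(cats)
            row[f"signature_{tissue}"] = sig.signature
            row[f"class_{tissue}"] = sig.broad_class
            row[f"null_only_{tissue}"] = cats == {"null"}
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def _truth_catmap(config: SimulationConfig) -> dict[int, str]:
    """Category of each true state from its emission row (threshold 0.5)."""
    E = config.emissions()
    out = {}
    for k in range(E.shape[0]):
        enriched = {MARK_ROLES[m] for m, p in zip(MARKS, E[k]) if p >= 0.5}
        if not enriched:
            out[k + 1] = "null"
        elif "active" in enriched and enriched & {"polycomb", "heterochromatin"}:
            out[k + 1] = "mixed"
        elif "active" in enriched:
            out[k + 1] = "active"
        elif "heterochromatin" in enriched:
            out[k + 1] = "heterochromatin"
        else:
            out[k + 1] = "polycomb"
    return out


# ------------------------------------------------------------ chromatin


def _sample_markov_path(
    n: int, A: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    K = A.shape[0]
    cum = A.cumsum(axis=1)
    u = rng.random(n)
    path = np.empty(n, dtype=np.int64)
    path[0] = rng.integers(0, K)
    for t in range(1, n):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def simulate_chromatin(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict, dict, dict, pd.DataFrame, list[Interval], list[str]]:
    """State paths, per-replicate mark masks and count tracks.

    One base state path is drawn per tissue and shared between the sexes;
    sex-discordant chromatin and the female S0 H4K16ac boost then modify
    the sexes independently.  Counts are Poisson(lambda_on) where the
    per-bin Bernoulli mark draw is on, Poisson(lambda_bg) otherwise;
    replicates redraw both the mark mask and the counts from the same
    state path.

    Returns (state_paths, mark_masks, tracks, gene_table, peak_intervals,
    s0_peak_gene_ids); ``gene_table`` carries the planted per-gene truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = list(genes) if genes is not None else []
    E = config.emissions()
    A = config.transition_matrix()
    K = E.shape[0]
    bs = config.bin_size
    catmap = _truth_catmap(config)
    # states used to plant sex-discordant chromatin; fall back to the
    # lowest-emission state when a category is absent from the truth
    null_state = int(np.argmin(E.sum(axis=1)))
    active_state = next(
        (k - 1 for k, c in catmap.items() if c == "active"), null_state
    )
    repressive_state = next(
        (k - 1 for k, c in catmap.items() if c in ("polycomb", "heterochromatin")),
        null_state,
    )

    n_bins = {c: genome.n_bins(c, bs) for c in genome.chrom_names}
    base_paths = {
        tissue: {c: _sample_markov_path(n_bins[c], A, rng) for c in genome.chrom_names}
        for tissue in TISSUES
    }
    # most transcribed gene bodies sit in active chromatin: overwrite a
    # configurable fraction of gene bodies with one active state per
    # tissue, so per-gene mark levels resemble expressed-gene coverage
    active_states = [k - 1 for k, c in catmap.items() if c == "active"]
    if genes and active_states and config.gene_active_fraction > 0:
        for g in genes:
            first, last = g.body.start // bs, (g.body.end - 1) // bs
            for tissue in TISSUES:
                if rng.random() < config.gene_active_fraction:
                    state = active_states[int(rng.integers(0, len(active_states)))]
                    base_paths[tissue][g.body.chrom][first : last + 1] = state
    state_paths = {
        (sex, tissue): {c: base_paths[tissue][c].copy() for c in n_bins}
        for sex in SEXES
        for tissue in TISSUES
    }

    # --- plant gene-level truth: bias labels, discordance, peak genes
    gene_table = _true_gene_classes(
        config, genome, genes, state_paths, catmap
    ) if genes else pd.DataFrame()
    if genes:
        ga = gene_table["region"].isin(["autosome", "PAR"])
        # sex bias is planted on transcribed genes only: a fold change on a
        # silent (null-chromatin) gene is invisible at any read depth
        eligible = ga & ~gene_table["null_only_gonad"]
        auto_ids = gene_table.index[eligible].to_numpy()
        n_bias = round(config.sex_biased_fraction * ga.sum())
        biased = rng.choice(auto_ids, size=min(n_bias, len(auto_ids)), replace=False)
        male_biased = set(biased[: n_bias // 2])
        female_biased = set(biased[n_bias // 2 :])
        gene_table["bias_gonad"] = "unbiased"
        gene_table.loc[sorted(male_biased), "bias_gonad"] = "male-biased"
        gene_table.loc[sorted(female_biased), "bias_gonad"] = "female-biased"
        gene_table.loc[~ga, "bias_gonad"] = "unbiased"

        gene_table["discordant_gonad"] = False
        gene_table["favored_sex"] = ""
        by_gene = {g.gene_id: g for g in genes}
        for gid in gene_table.index[ga]:
            bias = gene_table.at[gid, "bias_gonad"]
            frac = (
                config.discordant_fraction_biased
                if bias != "unbiased"
                else config.discordant_fraction_unbiased
            )
            if rng.random() >= frac:
                continue
            if bias == "male-biased":
                favored = "male"
            elif bias == "female-biased":
                favored = "female"
            else:
                favored = "male" if rng.random() < 0.5 else "female"
            other = "female" if favored == "male" else "male"
            g = by_gene[gid]
            first, last = g.body.start // bs, (g.body.end - 1) // bs
            sl = slice(first, last + 1)
            state_paths[(favored, "gonad")][g.body.chrom][sl] = active_state
            state_paths[(other, "gonad")][g.body.chrom][sl] = repressive_state
            gene_table.at[gid, "discordant_gonad"] = True
            gene_table.at[gid, "favored_sex"] = favored

    # --- planted H4K16ac peak blocks
    peak_intervals: list[Interval] = []
    s0_peak_ids: list[str] = []
    auto_peak_ids: list[str] = []
    if genes:
        # peak genes come from the transcriptionally active pool (the
        # machinery targets expressed genes); sampling counts are taken
        # against the full regional gene totals
        active_mask = gene_table["class_head"] == "active"
        s0_mask = gene_table["region"] == "S0"
        s0_pool = gene_table.index[s0_mask & active_mask].to_numpy()
        if len(s0_pool) == 0:
            s0_pool = gene_table.index[s0_mask].to_numpy()
        n_s0_peaks = min(
            round(config.s0_peak_gene_fraction * int(s0_mask.sum())), len(s0_pool)
        )
        s0_peak_ids = sorted(rng.choice(s0_pool, size=n_s0_peaks, replace=False))
        auto_mask = gene_table["region"] == "autosome"
        auto_pool = gene_table.index[auto_mask & active_mask].to_numpy()
        n_auto_peaks = min(
            round(config.autosome_peak_gene_fraction * int(auto_mask.sum())),
            len(auto_pool),
        )
        auto_peak_ids = sorted(rng.choice(auto_pool, size=n_auto_peaks, replace=False))
        by_gene = {g.gene_id: g for g in genes}
        for gid in s0_peak_ids + auto_peak_ids:
            g = by_gene[gid]
            # ground-truth peak locus: the gene body carrying the block
            peak_intervals.append(g.body)

    s0_bins = {c: np.zeros(n_bins[c], dtype=bool) for c in n_bins}
    for iv in genome.region_intervals("S0"):
        s0_bins[iv.chrom][iv.start // bs : -(-iv.end // bs)] = True
    # a peak gene carries H4K16ac along its whole body: the bursty
    # per-bin on/off draw is replaced by a uniform rate of
    # emission x lambda_on over every body bin, preserving the expected
    # per-gene total while making the signal one contiguous high-AUC
    # block (enrichment across the entire gene body).  S0 peaks exist
    # only in females (the compensation machinery's targets); autosomal
    # peaks are present in every sample.
    by_gene_all = {g.gene_id: g for g in genes}
    s0_peak_set = set(s0_peak_ids)
    h4_idx = MARKS.index("H4K16ac")
    gene_body_blocks: dict[tuple, list] = {
        (t, c): [] for t in TISSUES for c in n_bins
    }
    for gid in list(s0_peak_ids) + list(auto_peak_ids):
        gb = by_gene_all[gid].body
        first, last = gb.start // bs, (gb.end - 1) // bs
        for tissue in TISSUES:
            states = base_paths[tissue][gb.chrom][first : last + 1]
            p_mark = float(E[np.bincount(states, minlength=K).argmax(), h4_idx])
            gene_body_blocks[(tissue, gb.chrom)].append(
                (first, last, gid in s0_peak_set, max(p_mark, 0.05))
            )

    mark_masks: dict = {}
    tracks: dict = {}
    for mark in MARKS:
        mi = MARKS.index(mark)
        for sex in SEXES:
            for tissue in TISSUES:
                for rep in range(1, config.n_replicates(mark) + 1):
                    key = (mark, sex, tissue, rep)
                    masks = {}
                    values = {}
                    for chrom in genome.chrom_names:
                        path = state_paths[(sex, tissue)][chrom]
                        p = E[path, mi]
                        on = rng.random(len(path)) < p
                        lam = np.where(on, config.lambda_on, config.lambda_bg)
                        if mark == "H4K16ac":
                            lam = np.where(on, config.lambda_on, config.lambda_bg)
                            for first, last, female_only, p_mark in gene_body_blocks[(tissue, chrom)]:
                                if female_only and sex != "female":
                                    continue
                                lam[first : last + 1] = p_mark * config.lambda_on
                                on[first : last + 1] = True
                            if sex == "female":
                                lam = np.where(
                                    s0_bins[chrom], lam * config.h4k16ac_boost, lam
                                )
                        masks[chrom] = on
                        values[chrom] = rng.poisson(lam).astype(float)
                    mark_masks[key] = masks
                    tracks[key] = BinnedTrack(
                        mark=mark,
                        sample=SampleKey(sex, tissue, rep),
                        bin_size=bs,
                        values=values,
                        genome=genome,
                    )
    return state_paths, mark_masks, tracks, gene_table, peak_intervals, s0_peak_ids


# ----------------------------------------------------------- expression


def simulate_expression(
    config: SimulationConfig,
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation],
    gene_table: pd.DataFrame,
    s0_peak_gene_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """TPM matrix (genes x (sex, tissue, replicate) MultiIndex columns).

    Base abundance follows the gene's tissue chromatin class (the shared
    pre-discordance signature, so concordant chromatin drives expression
    while planted-unbiased discordant genes stay unbiased); sex-biased
    genes get +/- half the configured log2 fold change per sex in gonads;
    peak-overlapping S0 genes gain the peak bonus in both sexes; S0 genes
    have equal expected TPM in the two sexes (compensation).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    gene_ids = [g.gene_id for g in genes]
    if not gene_ids:
        return pd.DataFrame(
            index=gene_ids,
            columns=pd.MultiIndex.from_tuples(
                [], names=["sex", "tissue", "replicate"]
            ),
        )
    gene_effect = pd.Series(
        rng.normal(0, config.gene_log2_sd, size=len(gene_ids)), index=gene_ids
    )
    cols = pd.MultiIndex.from_tuples(
        [
            (sex, tissue, rep)
            for sex in SEXES
            for tissue in TISSUES
            for rep in range(1, config.replicates + 1)
        ],
        names=["sex", "tissue", "replicate"],
    )
    peak_bonus = pd.Series(0.0, index=gene_ids)
    peak_bonus[list(s0_peak_gene_ids)] = config.peak_log2_expr_bonus
    data = np.empty((len(gene_ids), len(cols)))
    for j, (sex, tissue, rep) in enumerate(cols):
        cls = gene_table[f"class_{tissue}"].copy()
        base = cls.map(config.class_log2_tpm)
        base[gene_table[f"null_only_{tissue}"]] = config.class_log2_tpm["null"]
        mu = base.loc[gene_ids] + gene_effect + peak_bonus
        if tissue == "gonad":
            bias = gene_table.loc[gene_ids, "bias_gonad"]
            shift = config.sex_bias_log2fc / 2
            sign = 1.0 if sex == "female" else -1.0
            mu = mu + sign * shift * (bias == "female-biased") - sign * shift * (
                bias == "male-biased"
            )
        noise = rng.normal(0, config.replicate_log2_sd, size=len(gene_ids))
        data[:, j] = np.exp2(mu.to_numpy(dtype=float) + noise)
    out = pd.DataFrame(data, index=gene_ids, columns=cols)
    return out.sort_index(axis=1)


# ------------------------------------------------------------- sequence


def simulate_sequences(
    config: SimulationConfig,
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Random uniform-composition sequence per chromosome (byte arrays)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        chrom: bases[rng.integers(0, 4, size=length)]
        for chrom, length in genome.chromosomes
    }


_RC = dict(zip(b"ACGT", b"TGCA"))


def plant_motif(
    config: SimulationConfig,
    sequences: dict[str, np.ndarray],
    peaks: Sequence[Interval],
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, str]]:
    """Insert motif occurrences in place; returns (chrom, start, strand).

    Background occurrences are planted uniformly per chromosome at
    ``motif_background_per_mb`` (times ``motif_s0_factor`` inside S0);
    additionally each S0 peak is filled until ``motif_peak_base_fraction``
    of its bases are motif.  Overlapping placements are dropped; a peak
    shorter than the motif is skipped with a warning.
    """
    import warnings

    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    fwd = np.frombuffer(config.motif.upper().encode(), dtype=np.uint8)
    rev = np.array([_RC[b] for b in fwd[::-1]], dtype=np.uint8)
    L = len(fwd)
    planted: list[tuple[str, int, str]] = []
    occupied: dict[str, set[int]] = {c: set() for c in sequences}

    def place(chrom: str, start: int) -> bool:
        span = range(start, start + L)
        occ = occupied[chrom]
        if any(p in occ for p in span):
            return False
        strand = "+" if rng.random() < 0.5 else "-"
        sequences[chrom][start : start + L] = fwd if strand == "+" else rev
        occ.update(span)
        planted.append((chrom, start, strand))
        return True

    s0_ivs = genome.region_intervals("S0")
    for chrom, length in genome.chromosomes:
        n_bg = rng.poisson(config.motif_background_per_mb * length / 1e6)
        for start in rng.integers(0, max(length - L, 1), size=n_bg):
            place(chrom, int(start))
        for iv in s0_ivs:
            if iv.chrom != chrom or config.motif_s0_factor <= 1:
                continue
            extra = config.motif_background_per_mb * (config.motif_s0_factor - 1)
            n_extra = rng.poisson(extra * iv.length / 1e6)
            for start in rng.integers(iv.start, max(iv.end - L, iv.start + 1), size=n_extra):
                place(chrom, int(start))
    s0_set = [(iv.start, iv.end, iv.chrom) for iv in s0_ivs]
    for peak in peaks:
        if peak.length < L:
            warnings.warn(f"peak {peak} shorter than motif; skipped")
            continue
        in_s0 = any(
            peak.chrom == c and peak.start >= s and peak.end <= e
            for s, e, c in s0_set
        )
        if not in_s0:
            continue
        target = int(config.motif_peak_base_fraction * peak.length / L)
        tries = 0
        n_placed = 0
        while n_placed < target and tries < 20 * target:
            start = int(rng.integers(peak.start, peak.end - L + 1))
            if place(peak.chrom, start):
                n_placed += 1
            tries += 1
    return planted


# ----------------------------------------------------------- orchestrator


def simulate_dataset(
    config: SimulationConfig, with_sequence: bool = False
) -> SyntheticDataset:
    """Full deterministic dataset from one config."""
    rng = np.random.default_rng(config.seed)
    genome, genes, tes = simulate_genome(config, rng)
    (
        state_paths,
        mark_masks,
        tracks,
        gene_table,
        peak_intervals,
        s0_peak_ids,
    ) = simulate_chromatin(config, genome, genes, rng)
    tpm = simulate_expression(config, genome, genes, gene_table, s0_peak_ids, rng)
    sequences = None
    motif_positions: list[tuple[str, int, str]] = []
    if with_sequence:
        sequences = simulate_sequences(config, genome, rng)
        motif_positions = plant_motif(config, sequences, peak_intervals, genome, rng)
    truth = GroundTruth(
        emissions=config.emissions(),
        transitions=config.transition_matrix(),
        state_paths=state_paths,
        mark_masks=mark_masks,
        gene_table=gene_table,
        peak_intervals=peak_intervals,
        s0_peak_gene_ids=list(s0_peak_ids),
        motif_positions=motif_positions,
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        tes=tes,
        tracks=tracks,
        tpm=tpm,
        truth=truth,
        sequences=sequences,
    )


def sequences_as_str(sequences: dict[str, np.ndarray]) -> dict[str, str]:
    return {c: s.tobytes().decode("ascii") for c, s in sequences.items()}
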