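"""Generative model of a Dam-reporter screen with planted ground truth.

The simulator emulates the full measurement chain:

1. a library of uniform-random randomized regions in one of the screen
   templates;
2. a planted sequence-effect model — log expression is the sum of
   per-position base weights, pairwise epistasis bonuses and Gaussian
   noise: ``log E = sum_p w[p, b_p] + sum_(i,j) e[i,j,b_i,b_j] + noise``;
3. a saturating methylation link ``m = E / (E + K_half)`` giving the
   probability that any one GATC site carries a full methyl mark, plus an
   optional hemimethylation fraction ``h`` (one-strand marks that resist
   both DpnI and MboI);
4. digestion survival: each of the 4 GATC sites must survive for a
   fragment to amplify. A site survives the MboI digestion if methylated
   or hemimethylated (probability h + (1 - h) m) and the DpnI digestion if
   unmethylated or hemimethylated (h + (1 - h)(1 - m)); sites are
   independent, so fragments survive with the 4th power;
5. sequencing: multinomial read sampling per pool (the uncut pool samples
   library abundance directly), optionally emitted as raw FASTQ-style
   reads in reverse-complement orientation with a uniform substitution
   error rate;
6. gene-specific RNA-seq reads with a planted per-variant 5'-UTR length
   (TSS) distribution.

Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readproc import CountTable
from .templates import ConstructTemplate, get_template, revcomp

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    ``positional_weights`` maps screen coordinate -> base -> natural-log
    expression contribution; ``epistasis_terms`` is a list of
    (coord_i, coord_j, {(base_i, base_j): weight}). ``k_half`` is the
    expression at half-maximal methylation ("median" centers it on the
    library median). ``class_log_e_threshold`` splits the planted
    high/low classes on log E.
    """

    screen_id: str = "promoter"
    n_variants: int = 1000
    positional_weights: dict = field(default_factory=dict)
    epistasis_terms: list = field(default_factory=list)
    noise_sd: float = 0.3
    k_half: float | str = "median"
    hemi_fraction: float = 0.0
    class_log_e_threshold: float = 0.0
    abundance_sd: float = 0.0       # lognormal DNA dosage spread (log10)
    error_rate: float = 0.0         # uniform substitution rate in reads

    def template(self) -> ConstructTemplate:
        return get_template(self.screen_id)


def default_promoter_config(n_variants: int = 1000, **kw) -> SimConfig:
    """Promoter screen with graded effects upstream of the Pribnow box.

    The five positions just upstream of the fixed TATAAT carry the main
    planted effects (A favorable, C unfavorable), the theoretical +1
    prefers purines, and one upstream pair interacts — mirroring the kind
    of structure these screens report, at effect sizes spanning roughly
    three decades of expression.
    """
    weights = {
        pos: {"A": 1.2, "T": 0.6, "G": 0.0, "C": -1.2}
        for pos in (-17, -16, -15, -14, -13)
    }
    weights[1] = {"A": 0.5, "G": 0.5, "C": -0.5, "T": -0.5}
    epi = [(-16, -15, {("A", "A"): 1.0})]
    return SimConfig(
        screen_id="promoter",
        n_variants=n_variants,
        positional_weights=weights,
        epistasis_terms=epi,
        noise_sd=0.3,
        **kw,
    )


def two_regime_promoter_config(n_variants: int = 4000, **kw) -> SimConfig:
    """Bimodal library: a strong extended-promoter pair switches regimes."""
    cfg = default_promoter_config(n_variants=n_variants, **kw)
    cfg.epistasis_terms = cfg.epistasis_terms + [
        (-19, -18, {("T", "G"): 4.6})
    ]
    cfg.class_log_e_threshold = 2.3
    return cfg


def default_utr_config(promoter: str = "strong", n_variants: int = 1000, **kw):
    """5'-UTR screen: the first randomized bases dominate, A/G favorable."""
    weights = {
        -25: {"A": 1.0, "G": 1.0, "C": -1.0, "T": -0.3},
        -3: {"A": 0.8, "T": 0.2, "G": -0.8, "C": 0.0},
        -1: {"T": 0.8, "A": 0.2, "G": -0.8, "C": 0.0},
    }
    return SimConfig(
        screen_id=f"utr_{promoter}",
        n_variants=n_variants,
        positional_weights=weights,
        noise_sd=0.3,
        **kw,
    )


def _coord_index(template: ConstructTemplate) -> dict[int, int]:
    return {c: i for i, c in enumerate(template.variant_positions)}


def simulate_library(config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Draw a random library and its ground truth.

    Returns a DataFrame indexed by variant sequence with columns log_e,
    expression, m (methylation probability), hemi_fraction, class_label
    and abundance.
    """
    template = config.template()
    L = template.variant_length
    rng = np.random.default_rng(seed)
    seqs = ["".join(row) for row in BASES[rng.integers(0, 4, size=(config.n_variants, L))]]
    # duplicate random variants are astronomically unlikely at these L, but
    # collapse them so the index is unique
    seqs = list(dict.fromkeys(seqs))
    coord_of = _coord_index(template)

    arr = np.array([list(s) for s in seqs])
    log_e = rng.normal(0.0, config.noise_sd, size=len(seqs))
    for coord, table in config.positional_weights.items():
        col = arr[:, coord_of[coord]]
        for base, w in table.items():
            log_e[col == base] += w
    for coord_i, coord_j, pair_table in config.epistasis_terms:
        ci, cj = arr[:, coord_of[coord_i]], arr[:, coord_of[coord_j]]
        for (bi, bj), w in pair_table.items():
            log_e[(ci == bi) & (cj == bj)] += w

    expression = np.exp(log_e)
    if config.k_half == "median":
        k_half = float(np.median(expression))
    else:
        k_half = float(config.k_half)
    m = expression / (expression + k_half)
    if config.abundance_sd > 0:
        abundance = 10 ** rng.normal(0.0, config.abundance_sd, size=len(seqs))
    else:
        abundance = np.ones(len(seqs))
    truth = pd.DataFrame(
        {
            "log_e": log_e,
            "expression": expression,
            "m": m,
            "hemi_fraction": config.hemi_fraction,
            "class_label": np.where(
                log_e > config.class_log_e_threshold, "high", "low"
            ),
            "abundance": abundance / abundance.sum(),
        },
        index=pd.Index(seqs, name="variant"),
    )
    truth.attrs["k_half"] = k_half
    truth.attrs["screen_id"] = config.screen_id
    truth.attrs["seed"] = seed
    return truth


N_GATC_SITES = 4


def survival_probabilities(m, h) -> tuple[np.ndarray, np.ndarray]:
    """P(fragment survives MboI), P(survives DpnI) for 4 independent sites."""
    m = np.asarray(m, dtype=float)
    site_mbo = h + (1.0 - h) * m          # methylated or hemi resists MboI
    site_dpn = h + (1.0 - h) * (1.0 - m)  # unmethylated or hemi resists DpnI
    return site_mbo ** N_GATC_SITES, site_dpn ** N_GATC_SITES


def simulate_digestion_counts(
    truth: pd.DataFrame, depth: int, seed: int = 0
) -> CountTable:
    """Multinomial read counts for the uncut, DpnI and MboI pools."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    abundance = truth["abundance"].to_numpy()
    p_mbo, p_dpn = survival_probabilities(
        truth["m"].to_numpy(), truth["hemi_fraction"].to_numpy()
    )
    pools = {}
    for cond, weight in (
        ("uncut", abundance),
        ("dpn", abundance * p_dpn),
        ("mbo", abundance * p_mbo),
    ):
        total = weight.sum()
        if total == 0:
            pools[cond] = np.zeros(len(truth), dtype=int)
        else:
            pools[cond] = rng.multinomial(depth, weight / total)
    counts = pd.DataFrame(pools, index=truth.index)
    return CountTable(counts=counts)


def _mutate(reads: list[str], rate: float, rng) -> list[str]:
    if rate <= 0:
        return reads
    out = []
    for read in reads:
        arr = np.array(list(read))
        hits = rng.random(len(arr)) < rate
        if hits.any():
            arr[hits] = BASES[rng.integers(0, 4, size=int(hits.sum()))]
        out.append("".join(arr))
    return out


def counts_to_reads(
    table: CountTable,
    template: ConstructTemplate,
    seed: int = 0,
    error_rate: float = 0.0,
) -> dict[str, list[str]]:
    """Expand a count table into shuffled raw reads per condition."""
    rng = np.random.default_rng(seed)
    pools = {}
    for cond in table.counts.columns:
        reads = []
        for variant, n in table.counts[cond].items():
            reads.extend([template.raw_read(variant)] * int(n))
        rng.shuffle(reads)
        pools[cond] = _mutate(reads, error_rate, rng)
    return pools


def planted_tss_distributions(
    truth: pd.DataFrame, seed: int = 0, minor_mass: float = 0.2,
    scatter_mass: float = 0.1,
) -> dict[str, dict[int, float]]:
    """Planted per-variant 5'-UTR length distributions.

    The dominant start follows the first randomized base: purines shift
    the TSS one base downstream (25-nt UTR, "N8"), pyrimidines keep the
    theoretical +1 (26-nt UTR, "N7"). The remainder of the mass goes to
    the alternative start and to one random shorter length.
    """
    rng = np.random.default_rng(seed)
    dists = {}
    major = 1.0 - minor_mass - scatter_mass
    for variant in truth.index:
        dominant = 25 if variant[0] in "AG" else 26
        minor = 51 - dominant
        scatter = int(rng.integers(15, 25))
        dist = {dominant: major, minor: minor_mass}
        dist[scatter] = dist.get(scatter, 0.0) + scatter_mass
        dists[variant] = dist
    return dists


def simulate_rnaseq(
    truth: pd.DataFrame,
    tss_dists: dict[str, dict[int, float]],
    depth: int,
    seed: int = 0,
    template: ConstructTemplate | None = None,
    barcode_length: int = 6,
    error_rate: float = 0.0,
) -> list[str]:
    """Gene-specific RNA-seq reads: barcode + UTR suffix + dam coding.

    Read counts are multinomial with weights proportional to RNA abundance
    (the planted expression) times the planted length distribution.
    """
    if template is None:
        template = get_template(truth.attrs.get("screen_id", "utr_strong"))
    rng = np.random.default_rng(seed)
    variants = list(truth.index)
    cells, weights = [], []
    expr = truth["expression"].to_numpy()
    for v, e in zip(variants, expr):
        for l, p in tss_dists[v].items():
            cells.append((v, l))
            weights.append(e * p)
    weights = np.asarray(weights)
    counts = rng.multinomial(depth, weights / weights.sum())
    coding = template.coding_context
    reads = []
    for (v, l), n in zip(cells, counts):
        if n == 0:
            continue
        utr_suffix = template.full_utr(v)[-l:]
        body = utr_suffix + coding[: max(0, 40 - l)]
        for _ in range(int(n)):
            barcode = "".join(BASES[rng.integers(0, 4, size=barcode_length)])
            reads.append(barcode + body)
    rng.shuffle(reads)
    return _mutate(reads, error_rate, rng)
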