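"""Ground-truthed synthetic data emulating transcription at ZGA.

Every input the analysis pipeline consumes can be generated here with known
truth: a toy genome with genes and repeats; stage/condition count tables with
planted maternal-decay, cluster-I (up), cluster-II (flat) and cluster-III
(down) features and a knockdown response concentrated in cluster III;
RNA fragment templates with a planted per-stage intergenic fraction that
peaks at the early two-cell stage and stays high in the knockdown;
histone-deposition fragments anti-correlated with expression change; Hi-C
contact pairs with a power-law distance decay and planted TAD squares of
known strength; FRAP recovery curves with known mobile fractions; and a
DAPI-normalised intensity table.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config seed plus a per-component tag, so identical configs produce
byte-identical output files regardless of which generators are invoked.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .expression import ExpressionMatrix
from .genome import (
    GenomeAnnotation,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_chrom_sizes,
    write_gtf_genes,
)
from .microscopy import RecoveryCurve

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_expression",
    "simulate_fragments",
    "simulate_deposition",
    "simulate_contacts",
    "simulate_frap",
    "simulate_intensity",
    "simulate_all",
    "intergenic_mask_per_base",
    "per_base_intergenic",
]

RNA_SAMPLES = ("MII.none", "early2C.control", "early2C.KD", "late2C.control", "late2C.KD")


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults set to the study conditions.

    Stage/condition keys follow ``stage.condition`` with stages
    ``1cell | MII | early2C | late2C`` and conditions ``none | control | KD``.
    """

    seed: int = 0

    # genome
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000}
    )
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    n_repeats: int = 250
    repeat_length_range: tuple[int, int] = (500, 5_000)
    intergenic_distance_bp: int = 10_000

    # expression (genes)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"maternal": 0.25, "I": 0.25, "II": 0.15, "III": 0.35}
    )
    r_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "maternal": (-3.3, -0.75),
            "I": (1.2, 3.2),
            "II": (-0.1, 0.1),
            "III": (-3.2, -1.2),
        }
    )
    kd_fold_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "maternal": (0.9, 1.1),
            "I": (0.5, 0.85),
            "II": (0.9, 1.1),
            "III": (2.0, 6.0),
        }
    )
    replicates: int = 3
    dispersion: float = 0.1
    counts_per_tpm_kb: float = 1.0
    pseudocount: float = 1.0

    # expression (repeats)
    repeat_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"I": 0.12, "II": 0.48, "III": 0.40}
    )
    repeat_library_size: int = 500_000

    # RNA fragments (intergenic-ratio inputs)
    fragments_per_sample: int = 20_000
    template_length_range: tuple[int, int] = (100, 500)
    intergenic_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "MII.none": 0.05,
            "early2C.control": 0.30,
            "late2C.control": 0.10,
            "late2C.KD": 0.28,
        }
    )

    # deposition fragments (metaprofile / correlation inputs)
    deposition_fragments: int = 40_000
    deposition_fragment_length: int = 150
    deposition_slope: float = 0.35
    deposition_noise_sd: float = 1.2

    # Hi-C
    bin_size: int = 100_000
    total_contacts: int = 1_200_000
    inter_fraction: float = 0.05
    tads_per_chrom: int = 5
    tad_length_bins: tuple[int, int] = (8, 15)
    tad_strengths: dict[str, list[float]] = field(
        default_factory=lambda: {
            "early2C.control": [1.5, 1.3, 1.2, 1.4, 1.1],
            "early2C.KD": [1.4, 1.2, 1.3, 1.1, 1.5],
            "late2C.control": [3.4, 3.0, 2.8, 1.8, 1.4],
            "late2C.KD": [2.0, 1.8, 1.6, 1.4, 1.2],
        }
    )

    # FRAP
    frap_mobile_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "1cell.none": 0.80,
            "early2C.control": 0.55,
            "early2C.KD": 0.60,
            "late2C.control": 0.30,
            "late2C.KD": 0.55,
        }
    )
    frap_bleach_floor: float = 0.35
    frap_rate_per_s: float = 0.25
    frap_noise_sd: float = 0.01
    frap_interval_s: float = 5.0
    frap_n_pre: int = 3
    frap_n_post: int = 10
    frap_curves_per_sample: int = 20

    # intensity table
    intensity_n_per_group: int = 20
    intensity_kd_fold: float = 0.35
    intensity_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        for key, frac in {**self.intergenic_fraction}.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"intergenic fraction for {key} outside [0, 1]")
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        for key, mf in self.frap_mobile_fraction.items():
            if not (0.0 <= mf <= 1.0):
                raise ValueError(f"FRAP mobile fraction for {key} outside [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    # -- (de)serialisation -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in (
            "gene_length_range",
            "repeat_length_range",
            "template_length_range",
            "tad_length_bins",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        for key in ("r_ranges", "kd_fold_ranges"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _rng(config: SimulationConfig, *tags: str) -> np.random.Generator:
    """Independent, order-insensitive child generator for one component."""
    keys = [int(config.seed) & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def intergenic_mask_per_base(size: int, genes: np.ndarray, distance_bp: int) -> np.ndarray:
    """Per-base oracle: True where the nearest gene base is > distance_bp away.

    Independent of the interval-arithmetic derivation: computes an explicit
    distance-to-nearest-gene-base transform over the chromosome.
    """
    gene_mask = np.zeros(size, dtype=bool)
    for s, e in np.asarray(genes, dtype=np.int64).reshape(-1, 2):
        gene_mask[s:e] = True
    if not gene_mask.any():
        return np.ones(size, dtype=bool)
    pos = np.arange(size, dtype=np.int64)
    far = 2 * size
    prev = np.where(gene_mask, pos, -far)
    np.maximum.accumulate(prev, out=prev)
    dist_prev = pos - prev
    nxt = np.where(gene_mask, pos, 3 * far)
    nxt = nxt[::-1]
    np.minimum.accumulate(nxt, out=nxt)
    dist_next = nxt[::-1] - pos
    dist = np.minimum(dist_prev, dist_next)
    return dist > distance_bp


def _mask_to_intervals(mask: np.ndarray) -> np.ndarray:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8), [0]])))
    return edges.reshape(-1, 2)


def per_base_intergenic(annotation: GenomeAnnotation, distance_bp: int) -> IntervalSet:
    """Intergenic regions via the per-base oracle (ground truth for tests)."""
    out: dict[str, np.ndarray] = {}
    for chrom, size in annotation.chrom_sizes.items():
        genes = np.array(
            [(g.start, g.end) for g in annotation.genes if g.chrom == chrom], dtype=np.int64
        ).reshape(-1, 2)
        mask = intergenic_mask_per_base(size, genes, distance_bp)
        ivs = _mask_to_intervals(mask)
        if len(ivs):
            out[chrom] = ivs
    return IntervalSet(out, tag=f"intergenic, d={distance_bp} (per-base oracle)")


def _place_features(
    rng: np.random.Generator, size: int, lengths: np.ndarray, min_gap: int = 1
) -> np.ndarray:
    """Place non-overlapping features of given lengths uniformly on [0, size)."""
    n = len(lengths)
    free = size - int(lengths.sum()) - (n + 1) * min_gap
    if free < 0:
        raise ValueError("infeasible feature density for chromosome")
    cuts = np.sort(rng.integers(0, free + 1, size=n + 1))
    gaps = np.diff(np.concatenate([[0], cuts])) + min_gap
    order = rng.permutation(n)
    starts = np.empty(n, dtype=np.int64)
    cursor = 0
    for k, idx in enumerate(order):
        cursor += gaps[k]
        starts[idx] = cursor
        cursor += lengths[idx]
    return starts


_BIOTYPES = ("protein_coding", "lncRNA", "pseudogene")
_BIOTYPE_P = (0.8, 0.1, 0.1)
_REPEAT_FAMILIES = ("LINE_L1", "ERVK", "ERVL", "SINE_B1", "MERVL")


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, IntervalSet]:
    """Toy genome: non-overlapping genes, repeats, and true intergenic regions.

    The returned intergenic set is computed by the per-base distance oracle,
    independently of :func:`zgakit.genome.derive_intergenic_regions`.
    """
    rng = _rng(config, "genome")
    sizes = config.chrom_sizes
    total = sum(sizes.values())
    genes: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    gene_counter = 0
    repeat_counter = 0
    chroms = list(sizes)
    n_gene_by_chrom = _split_counts(config.n_genes, [sizes[c] / total for c in chroms])
    n_rep_by_chrom = _split_counts(config.n_repeats, [sizes[c] / total for c in chroms])
    for chrom, n_g, n_r in zip(chroms, n_gene_by_chrom, n_rep_by_chrom):
        lengths = rng.integers(*config.gene_length_range, size=n_g, endpoint=True)
        starts = _place_features(rng, sizes[chrom], lengths)
        order = np.argsort(starts)
        for s, l in zip(starts[order], lengths[order]):
            gene_counter += 1
            biotype = _BIOTYPES[rng.choice(len(_BIOTYPES), p=_BIOTYPE_P)]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GenomicInterval(chrom, int(s), int(s + l), name=f"g{gene_counter:04d}",
                                feature_class=biotype, strand=strand)
            )
        rep_lengths = rng.integers(*config.repeat_length_range, size=n_r, endpoint=True)
        rep_starts = rng.integers(0, sizes[chrom] - config.repeat_length_range[1], size=n_r)
        for s, l in zip(np.sort(rep_starts), rep_lengths):
            repeat_counter += 1
            fam = _REPEAT_FAMILIES[rng.integers(len(_REPEAT_FAMILIES))]
            repeats.append(
                GenomicInterval(chrom, int(s), int(s + l), name=f"r{repeat_counter:04d}",
                                feature_class=fam)
            )
    annotation = GenomeAnnotation(chrom_sizes=dict(sizes), genes=genes, repeats=repeats)
    truth = per_base_intergenic(annotation, config.intergenic_distance_bp)
    return annotation, truth


def _split_counts(n: int, weights: Sequence[float]) -> list[int]:
    raw = [int(round(n * w)) for w in weights]
    raw[-1] += n - sum(raw)
    return raw


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTables:
    counts: ExpressionMatrix
    truth: pd.DataFrame  # index gene_id; class, log2_ratio, kd_fold, tpm_* columns
    repeat_counts: ExpressionMatrix
    repeat_truth: pd.DataFrame


def _assign_classes(
    rng: np.random.Generator, n: int, fractions: Mapping[str, float]
) -> np.ndarray:
    labels = list(fractions)
    counts = _split_counts(n, [fractions[c] for c in labels])
    arr = np.repeat(labels, counts)
    rng.shuffle(arr)
    return arr


def _shift_to_budget(early: np.ndarray, r_target: np.ndarray, budget: float, pc: float) -> float:
    """Global shift delta so that sum((early+pc)*2^(r+delta) - pc) == budget.

    Shifting every planted log2 ratio by one scalar keeps relative effects
    intact while making the late column renormalise exactly to the TPM/CPM
    budget, so planted ratios survive measurement unchanged.
    """

    def f(delta: float) -> float:
        late = np.maximum((early + pc) * np.power(2.0, r_target + delta) - pc, 0.0)
        return late.sum() - budget

    return float(brentq(f, -2.0, 2.0, xtol=1e-12))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return np.rint(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def _planted_mean_columns(
    rng: np.random.Generator,
    classes: np.ndarray,
    config: SimulationConfig,
    with_mii: bool,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-feature mean abundance (TPM/CPM scale) per sample, plus realized
    log2 ratios (pseudocount space) and KD folds."""
    n = len(classes)
    pc = config.pseudocount
    early = np.empty(n)
    early[classes == "maternal"] = rng.uniform(50, 300, (classes == "maternal").sum())
    early[classes == "I"] = rng.uniform(15, 100, (classes == "I").sum())
    early[classes == "II"] = rng.uniform(8, 100, (classes == "II").sum())
    early[classes == "III"] = rng.uniform(30, 150, (classes == "III").sum())
    # maternal "early" drawn above is the MII-scale abundance; its early2C
    # value is a fixed decay of MII, imposed after anchoring (below)
    mat = classes == "maternal"
    mii_over_early = np.ones(n)
    if with_mii and mat.any():
        mii_over_early[mat] = 1.0 / rng.uniform(0.3, 0.7, mat.sum())

    early *= 1e6 / early.sum()  # anchor: early column is exactly on budget

    r_target = np.empty(n)
    for cls, rng_pair in config.r_ranges.items():
        m = classes == cls
        if m.any():
            r_target[m] = rng.uniform(rng_pair[0], rng_pair[1], m.sum())
    delta = _shift_to_budget(early, r_target, 1e6, pc)
    if abs(delta) > 0.28:
        raise RuntimeError(
            f"planted-ratio budget shift {delta:.3f} too large; "
            "class fractions and ratio ranges are inconsistent"
        )
    r = r_target + delta
    late = np.maximum((early + pc) * np.power(2.0, r) - pc, 0.0)

    # MII column: maternal genes sit above their early2C value; everything
    # else is near-silent in the oocyte. Rescaled to budget afterwards.
    mii_raw = np.where(mat, early * mii_over_early, rng.uniform(0.0, 3.0, n))
    lam = 1e6 / mii_raw.sum()
    mii = mii_raw * lam
    if with_mii:
        if mat.any():
            margin = np.log2(mii[mat] / np.maximum(early[mat], 1e-12))
            if (margin < 0.1).any():
                raise RuntimeError("maternal decay margin lost after MII renormalisation")
            late_margin = r[mat]
            if (late_margin > -0.15).any():
                raise RuntimeError("maternal late2C decay margin lost")
        if (mii[~mat] >= early[~mat]).any():
            raise RuntimeError("non-maternal MII abundance exceeds early2C abundance")

    kd_fold = np.empty(n)
    for cls, pair in config.kd_fold_ranges.items():
        m = classes == cls
        if m.any():
            kd_fold[m] = rng.uniform(pair[0], pair[1], m.sum())
    means = pd.DataFrame(
        {
            "MII.none": mii,
            "early2C.control": early,
            "early2C.KD": early,
            "late2C.control": late,
            "late2C.KD": late * kd_fold,
        }
    )
    if not with_mii:
        means = means.drop(columns=["MII.none"])
    return means, r, kd_fold


def simulate_expression(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> ExpressionTables:
    """Count tables for genes (TPM scale) and repeats (CPM scale) with truth.

    Planted structure: maternal genes decay strictly through MII -> early
    two-cell -> late two-cell; cluster I rises between the two-cell stages
    (mildly reduced by the knockdown), cluster II is flat, cluster III is a
    minor-ZGA burst that is silenced in late control embryos but stays high
    under H3.1/3.2 knockdown. Counts are negative-binomial around
    length-scaled means; ``dispersion == 0`` yields deterministic rounded
    means. Planted log2(late/early) ratios sit at least 0.1 away from the
    +-0.5 thresholds by construction.
    """
    rng = _rng(config, "expression")
    gene_ids = [g.name for g in annotation.genes]
    lengths = pd.Series({g.name: float(len(g)) for g in annotation.genes})
    classes = _assign_classes(rng, len(gene_ids), config.class_fractions)
    means, r, kd_fold = _planted_mean_columns(rng, classes, config, with_mii=True)
    means.index = pd.Index(gene_ids, name="feature_id")

    cols = {}
    for sample in RNA_SAMPLES:
        mu = means[sample].to_numpy() * (lengths.to_numpy() / 1000.0) * config.counts_per_tpm_kb
        for rep in range(1, config.replicates + 1):
            cols[f"{sample}.rep{rep}"] = _nb_counts(rng, mu, config.dispersion)
    counts = ExpressionMatrix(
        data=pd.DataFrame(cols, index=means.index), lengths=lengths, unit="counts"
    )
    truth = pd.DataFrame(
        {
            "class": classes,
            "log2_ratio": r,
            "kd_fold": kd_fold,
            **{f"tpm_{c}": means[c] for c in means.columns},
        },
        index=means.index,
    )

    # repeats: CPM scale, no maternal class, same clustering scheme
    rep_ids = [rep.name for rep in annotation.repeats]
    rep_classes = _assign_classes(rng, len(rep_ids), config.repeat_class_fractions)
    rep_means, rep_r, rep_kd = _planted_mean_columns(rng, rep_classes, config, with_mii=False)
    rep_means.index = pd.Index(rep_ids, name="feature_id")
    rep_cols = {}
    for sample in ("early2C.control", "late2C.control", "late2C.KD"):
        mu = rep_means[sample].to_numpy() / 1e6 * config.repeat_library_size
        for rep in range(1, config.replicates + 1):
            rep_cols[f"{sample}.rep{rep}"] = _nb_counts(rng, mu, config.dispersion)
    repeat_counts = ExpressionMatrix(
        data=pd.DataFrame(rep_cols, index=rep_means.index), unit="counts"
    )
    repeat_truth = pd.DataFrame(
        {
            "class": rep_classes,
            "log2_ratio": rep_r,
            "kd_fold": rep_kd,
            **{f"cpm_{c}": rep_means[c] for c in rep_means.columns},
        },
        index=rep_means.index,
    )
    return ExpressionTables(counts, truth, repeat_counts, repeat_truth)


# ---------------------------------------------------------------------------
# RNA fragments
# ---------------------------------------------------------------------------


def simulate_fragments(
    config: SimulationConfig,
    sample: str,
    annotation: GenomeAnnotation,
    intergenic: IntervalSet,
) -> pd.DataFrame:
    """Fragment templates for one sample, with a per-fragment intergenic flag.

    Each template is intergenic with the configured per-sample probability,
    in which case it is placed fully inside a uniformly chosen intergenic
    interval (intervals too short for the drawn template are redrawn);
    otherwise it is placed overlapping a uniformly chosen gene. Template
    lengths are uniform over ``template_length_range``.
    """
    if sample not in config.intergenic_fraction:
        raise KeyError(f"no intergenic fraction configured for sample {sample!r}")
    frac = config.intergenic_fraction[sample]
    rng = _rng(config, "fragments", sample)
    lo, hi = config.template_length_range
    n = config.fragments_per_sample
    iv_list = list(intergenic.intervals())
    if frac > 0 and not iv_list:
        raise ValueError("no intergenic intervals available for placement")
    genes = annotation.genes
    rows = []
    for k in range(n):
        tlen = int(rng.integers(lo, hi, endpoint=True))
        is_inter = bool(rng.random() < frac)
        if is_inter:
            while True:
                iv = iv_list[int(rng.integers(len(iv_list)))]
                if len(iv) >= tlen:
                    break
                tlen = int(rng.integers(lo, hi, endpoint=True))
            start = int(rng.integers(iv.start, iv.end - tlen, endpoint=True))
            chrom = iv.chrom
        else:
            g = genes[int(rng.integers(len(genes)))]
            chrom = g.chrom
            size = annotation.chrom_sizes[chrom]
            start = int(rng.integers(max(0, g.start - tlen + 1), min(g.end, size - tlen) - 1,
                                     endpoint=True))
        rows.append((chrom, start, start + tlen, f"{sample}.f{k:06d}", int(is_inter)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "intergenic"])


def simulate_deposition(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histone-deposition fragments anti-correlated with expression change.

    Per-gene sampling weight is ``length * exp(-slope * log2_ratio + noise)``,
    so genes repressed between the two-cell stages (cluster III) carry more
    deposition than induced genes (cluster I), giving a negative
    deposition-vs-change correlation of moderate size. Returns the fragment
    table and the per-gene planted weight table.
    """
    rng = _rng(config, "deposition")
    genes = [g for g in annotation.genes if len(g) > config.deposition_fragment_length]
    r = truth.loc[[g.name for g in genes], "log2_ratio"].to_numpy()
    noise = rng.normal(0.0, config.deposition_noise_sd, len(genes))
    log_w = -config.deposition_slope * r + noise
    weights = np.array([len(g) for g in genes]) * np.exp(log_w)
    p = weights / weights.sum()
    idx = rng.choice(len(genes), size=config.deposition_fragments, p=p)
    flen = config.deposition_fragment_length
    rows = []
    for k, gi in enumerate(idx):
        g = genes[gi]
        start = int(rng.integers(g.start, g.end - flen, endpoint=True))
        rows.append((g.chrom, start, start + flen, f"dep.f{k:06d}"))
    frags = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    gene_truth = pd.DataFrame(
        {"gene_id": [g.name for g in genes], "planted_weight": weights, "log2_ratio": r}
    ).set_index("gene_id")
    return frags, gene_truth


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------


def plant_tads(config: SimulationConfig) -> list[GenomicInterval]:
    """TAD locations shared by all samples (locations are conserved; only
    strengths vary by stage/condition)."""
    rng = _rng(config, "tads")
    lo, hi = config.tad_length_bins
    out: list[GenomicInterval] = []
    counter = 0
    for chrom, size in config.chrom_sizes.items():
        n_bins = size // config.bin_size
        margin = hi + 1  # room for a full flank window on both sides
        cursor = margin
        placed = 0
        lengths = rng.integers(lo, hi, size=config.tads_per_chrom, endpoint=True)
        # spread domains over the usable span with gaps >= their own length
        span = n_bins - 2 * margin
        need = int(lengths.sum() * 2)
        if need > span:
            raise ValueError("TADs do not fit chromosome; reduce count or lengths")
        slack = span - need
        gaps = rng.multinomial(slack, np.ones(config.tads_per_chrom) / config.tads_per_chrom)
        for L, gap in zip(lengths, gaps):
            cursor += int(gap)
            a = cursor
            b = a + int(L)
            counter += 1
            out.append(
                GenomicInterval(
                    chrom,
                    a * config.bin_size,
                    b * config.bin_size,
                    name=f"tad{counter:03d}",
                )
            )
            cursor = b + int(L)  # leave at least one TAD length between domains
            placed += 1
    return out


def simulate_contacts(
    config: SimulationConfig,
    sample: str,
    tads: Sequence[GenomicInterval] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson-sampled contact pairs with planted TAD squares for one sample.

    Background contact probability decays as ``(1 + |i - j|)^-1`` per bin
    pair; within each planted TAD square the rate is multiplied by that TAD's
    strength. A configured fraction of contacts is inter-chromosomal.
    Returns ``(records, tad_truth)`` where records follow the pairs-like
    5-column layout.
    """
    if config.total_contacts <= 0:
        raise ValueError("contact depth must be positive")
    if sample not in config.tad_strengths:
        raise KeyError(f"no TAD strengths configured for sample {sample!r}")
    if tads is None:
        tads = plant_tads(config)
    strengths = config.tad_strengths[sample]
    rng = _rng(config, "contacts", sample)
    sizes = config.chrom_sizes
    total = sum(sizes.values())
    cis_total = config.total_contacts * (1.0 - config.inter_fraction)
    frames = []
    truth_rows = []
    tad_idx = 0
    for chrom, size in sizes.items():
        n = size // config.bin_size
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        rate = 1.0 / (1.0 + d)
        chrom_tads = [t for t in tads if t.chrom == chrom]
        for t in chrom_tads:
            s = float(strengths[tad_idx % len(strengths)])
            tad_idx += 1
            a, b = t.start // config.bin_size, t.end // config.bin_size
            rate[a:b, a:b] *= s
            truth_rows.append(
                {"chrom": t.chrom, "start": t.start, "end": t.end, "name": t.name,
                 "strength": s}
            )
        upper = np.triu_indices(n)
        weight = rate[upper]
        depth = cis_total * (size / total)
        mu = weight / weight.sum() * depth
        counts = rng.poisson(mu)
        nz = counts > 0
        i, j = upper[0][nz], upper[1][nz]
        pos1 = i * config.bin_size + config.bin_size // 2
        pos2 = j * config.bin_size + config.bin_size // 2
        frames.append(
            pd.DataFrame(
                {"chrom1": chrom, "pos1": pos1, "chrom2": chrom, "pos2": pos2,
                 "count": counts[nz]}
            )
        )
    # inter-chromosomal background
    n_inter = int(rng.poisson(config.total_contacts * config.inter_fraction))
    if n_inter and len(sizes) > 1:
        chroms = list(sizes)
        probs = np.array([sizes[c] for c in chroms], dtype=float)
        probs /= probs.sum()
        c1 = rng.choice(len(chroms), size=n_inter, p=probs)
        c2 = rng.choice(len(chroms), size=n_inter, p=probs)
        redo = c1 == c2
        while redo.any():
            c2[redo] = rng.choice(len(chroms), size=int(redo.sum()), p=probs)
            redo = c1 == c2
        pos1 = np.array([rng.integers(sizes[chroms[k]]) for k in c1])
        pos2 = np.array([rng.integers(sizes[chroms[k]]) for k in c2])
        frames.append(
            pd.DataFrame(
                {"chrom1": [chroms[k] for k in c1], "pos1": pos1,
                 "chrom2": [chroms[k] for k in c2], "pos2": pos2,
                 "count": np.ones(n_inter, dtype=int)}
            )
        )
    records = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# FRAP and intensity
# ---------------------------------------------------------------------------


def simulate_frap(
    config: SimulationConfig, sample: str
) -> tuple[list[RecoveryCurve], float]:
    """Recovery curves for one sample with the configured true mobile fraction.

    Pre-bleach frames sit at 1.0; the first post-bleach frame is at the
    bleach floor; recovery rises exponentially toward
    ``F0 + MF * (1 - F0)`` at the configured rate, with Gaussian noise.
    """
    if sample not in config.frap_mobile_fraction:
        raise KeyError(f"no FRAP mobile fraction configured for sample {sample!r}")
    mf = config.frap_mobile_fraction[sample]
    rng = _rng(config, "frap", sample)
    dt = config.frap_interval_s
    curves = []
    for _ in range(config.frap_curves_per_sample):
        f0 = config.frap_bleach_floor
        t_pre = np.arange(config.frap_n_pre) * dt
        t_rec = np.arange(config.frap_n_post) * dt
        pre = np.ones(config.frap_n_pre)
        rec = f0 + mf * (1.0 - f0) * (1.0 - np.exp(-config.frap_rate_per_s * t_rec))
        t = np.concatenate([t_pre, t_pre[-1] + 2 * dt + t_rec])
        y = np.concatenate([pre, rec])
        if config.frap_noise_sd > 0:
            y = y + rng.normal(0.0, config.frap_noise_sd, len(y))
        curves.append(
            RecoveryCurve(t, y, bleach_index=config.frap_n_pre, n_pre=config.frap_n_pre)
        )
    return curves, mf


def simulate_intensity(config: SimulationConfig) -> pd.DataFrame:
    """Per-embryo signal/DAPI intensity table for control vs KD groups.

    The knockdown group's H3.1/3.2 signal sits at ``intensity_kd_fold`` of
    the control ratio, with lognormal embryo-to-embryo noise.
    """
    rng = _rng(config, "intensity")
    rows = []
    for group, fold in (("control", 1.0), ("KD", config.intensity_kd_fold)):
        for k in range(config.intensity_n_per_group):
            dapi = 100.0 * rng.lognormal(0.0, 0.1)
            ratio = fold * rng.lognormal(0.0, config.intensity_noise_sd)
            rows.append(
                {"embryo_id": f"{group}{k:02d}", "group": group,
                 "signal": ratio * dapi, "dapi": dapi}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-dataset orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    intergenic_truth: IntervalSet
    expression: ExpressionTables
    fragments: dict[str, pd.DataFrame]
    deposition: pd.DataFrame
    deposition_truth: pd.DataFrame
    contacts: dict[str, pd.DataFrame]
    tads: list[GenomicInterval]
    tad_truth: dict[str, pd.DataFrame]
    frap: dict[str, tuple[list[RecoveryCurve], float]]
    intensity: pd.DataFrame


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Generate every pipeline input; optionally write the file bundle.

    Emitted layout (all plain text)::

        genome/{genes.bed,genes.gtf,repeats.bed,chrom.sizes,intergenic_true.bed}
        expression/{gene_counts.tsv,repeat_counts.tsv}
        fragments/<sample>.bed           rna fragment templates
        deposition/fragments.bed
        hic/{tads.bed,<sample>.pairs.tsv}
        frap/<sample>.curve<k>.tsv
        intensity/intensity.tsv
        truth/*.tsv                      planted ground truth sidecars
        config.yaml
    """
    annotation, intergenic_truth = simulate_genome(config)
    expr = simulate_expression(config, annotation)
    fragments = {
        s: simulate_fragments(config, s, annotation, intergenic_truth)
        for s in config.intergenic_fraction
    }
    dep_frags, dep_truth = simulate_deposition(config, annotation, expr.truth)
    tads = plant_tads(config)
    contacts: dict[str, pd.DataFrame] = {}
    tad_truth: dict[str, pd.DataFrame] = {}
    for s in config.tad_strengths:
        contacts[s], tad_truth[s] = simulate_contacts(config, s, tads)
    frap = {s: simulate_frap(config, s) for s in config.frap_mobile_fraction}
    intensity = simulate_intensity(config)
    ds = SimulatedDataset(
        config=config,
        annotation=annotation,
        intergenic_truth=intergenic_truth,
        expression=expr,
        fragments=fragments,
        deposition=dep_frags,
        deposition_truth=dep_truth,
        contacts=contacts,
        tads=tads,
        tad_truth=tad_truth,
        frap=frap,
        intensity=intensity,
    )
    if outdir is not None:
        write_dataset(ds, Path(outdir))
    return ds


def write_dataset(ds: SimulatedDataset, outdir: Path) -> None:
    from .expression import write_counts_table, write_fragments_bed
    from .contacts import write_contacts
    from .microscopy import write_recovery_curve

    outdir = Path(outdir)
    for sub in ("genome", "expression", "fragments", "deposition", "hic", "frap",
                "intensity", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    ds.config.to_yaml(outdir / "config.yaml")
    write_bed(ds.annotation.genes, outdir / "genome" / "genes.bed")
    write_gtf_genes(ds.annotation.genes, outdir / "genome" / "genes.gtf")
    write_bed(ds.annotation.repeats, outdir / "genome" / "repeats.bed")
    write_chrom_sizes(ds.annotation.chrom_sizes, outdir / "genome" / "chrom.sizes")
    ds.intergenic_truth.to_bed(outdir / "genome" / "intergenic_true.bed")
    write_counts_table(ds.expression.counts, outdir / "expression" / "gene_counts.tsv")
    write_counts_table(ds.expression.repeat_counts, outdir / "expression" / "repeat_counts.tsv")
    ds.expression.truth.to_csv(outdir / "truth" / "gene_truth.tsv", sep="\t",
                               float_format="%.8g")
    ds.expression.repeat_truth.to_csv(outdir / "truth" / "repeat_truth.tsv", sep="\t",
                                      float_format="%.8g")
    for sample, frags in ds.fragments.items():
        write_fragments_bed(frags, outdir / "fragments" / f"{sample}.bed")
        frags[["name", "intergenic"]].to_csv(
            outdir / "truth" / f"fragments.{sample}.tsv", sep="\t", index=False
        )
    write_fragments_bed(ds.deposition, outdir / "deposition" / "fragments.bed")
    ds.deposition_truth.to_csv(outdir / "truth" / "deposition_genes.tsv", sep="\t",
                               float_format="%.8g")
    write_bed(ds.tads, outdir / "hic" / "tads.bed")
    for sample, rec in ds.contacts.items():
        write_contacts(rec, outdir / "hic" / f"{sample}.pairs.tsv")
        ds.tad_truth[sample].to_csv(outdir / "truth" / f"tads.{sample}.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    for sample, (curves, mf) in ds.frap.items():
        for k, curve in enumerate(curves):
            write_recovery_curve(curve, outdir / "frap" / f"{sample}.curve{k:02d}.tsv")
        with open(outdir / "truth" / f"frap.{sample}.tsv", "w") as fh:
            fh.write(f"sample\ttrue_mobile_fraction\n{sample}\t{mf:.6g}\n")
    ds.intensity.to_csv(outdir / "intensity" / "intensity.tsv", sep="\t", index=False,
                        float_format="%.8g")
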