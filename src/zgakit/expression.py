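"""Expression quantification and clustering across zygotic genome activation.

Implements the bulk RNA-seq arm of the pipeline: TPM/CPM normalisation,
exclusion of decaying maternal transcripts, fold-change clustering of
embryo-transcribed features between the early and late two-cell stages,
knockdown response summaries, the intergenic-read ratio, scale-regions
deposition metaprofiles (RPKM), and the deposition-vs-expression-change
Spearman correlation.

Cluster semantics on ``r = log2((late + pc) / (early + pc))`` with the
default pseudocount ``pc = 1``:

* cluster I (increase): ``r > 0.5``
* cluster II (little change): ``-0.5 < r < 0.5``
* cluster III (decrease): ``r < -0.5``

Both threshold inequalities are strict; a feature landing exactly on a
threshold falls into cluster II.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClusterAssignment",
    "DepositionProfile",
    "compute_tpm",
    "compute_cpm",
    "exclude_maternal",
    "assign_clusters",
    "kd_response",
    "intergenic_ratio",
    "metaprofile",
    "gene_body_density",
    "spearman_deposition_vs_change",
    "read_counts_table",
    "write_counts_table",
    "read_fragments_bed",
    "write_fragments_bed",
]

CLUSTERS = ("I", "II", "III")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with optional feature lengths.

    ``data`` rows are features, columns are sample labels (conventionally
    ``stage.condition.repN``). ``unit`` is one of ``counts``, ``TPM``,
    ``CPM``. Lengths (bp) are required only for TPM computation.
    """

    data: pd.DataFrame
    lengths: pd.Series | None = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundance values must be >= 0")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.data.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()][:5].tolist()
                raise ValueError(f"missing lengths for features {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def compute_tpm(em: ExpressionMatrix) -> ExpressionMatrix:
    """Length-normalised transcripts-per-million; every column sums to 1e6."""
    if em.lengths is None:
        raise ValueError("TPM requires feature lengths")
    if (em.lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    rates = em.data.div(em.lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(data=tpm, lengths=em.lengths, unit="TPM")


def compute_cpm(em: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million (no length normalisation); columns sum to 1e6."""
    totals = em.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    cpm = em.data.div(totals, axis=1) * 1e6
    return ExpressionMatrix(data=cpm, lengths=em.lengths, unit="CPM")


def exclude_maternal(
    tpm: pd.DataFrame,
    mii: str = "MII",
    early: str = "early2C",
    late: str = "late2C",
    mode: str = "strict_all",
) -> pd.Index:
    """Identify maternally-deposited, decaying transcripts to drop.

    A gene is flagged when its expression keeps falling from the oocyte
    through the late two-cell stage, i.e. ``TPM(MII) > TPM(early2C) >
    TPM(late2C)`` with strict inequalities (``mode="strict_all"``). The
    looser reading ``mode="ends_only"`` flags ``TPM(MII) > TPM(late2C)``
    regardless of the early two-cell value. Everything not flagged is the
    group of genes transcribed in the embryo.
    """
    for col in (mii, early, late):
        if col not in tpm.columns:
            raise ValueError(f"missing stage column {col!r}")
    if mode == "strict_all":
        mask = (tpm[mii] > tpm[early]) & (tpm[early] > tpm[late])
    elif mode == "ends_only":
        mask = tpm[mii] > tpm[late]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return tpm.index[mask]


@dataclass
class ClusterAssignment:
    """Per-feature fold-change cluster labels with the ratios behind them."""

    table: pd.DataFrame  # columns: log2_ratio, cluster
    lo: float = -0.5
    hi: float = 0.5
    pseudocount: float = 1.0

    def members(self, cluster: str) -> pd.Index:
        return self.table.index[self.table["cluster"] == cluster]

    def sizes(self) -> dict[str, int]:
        counts = self.table["cluster"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLUSTERS}

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def assign_clusters(
    early: pd.Series,
    late: pd.Series,
    lo: float = -0.5,
    hi: float = 0.5,
    pseudocount: float = 1.0,
) -> ClusterAssignment:
    """Cluster features by ``log2((late + pc)/(early + pc))`` fold change."""
    early, late = early.align(late, join="inner")
    if (early < 0).any() or (late < 0).any():
        raise ValueError("abundances must be non-negative")
    r = np.log2((late + pseudocount) / (early + pseudocount))
    cluster = pd.Series("II", index=r.index, dtype=object)
    cluster[r > hi] = "I"
    cluster[r < lo] = "III"
    table = pd.DataFrame({"log2_ratio": r, "cluster": cluster})
    return ClusterAssignment(table=table, lo=lo, hi=hi, pseudocount=pseudocount)


def kd_response(
    kd: pd.Series,
    ctrl: pd.Series,
    clusters: ClusterAssignment,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature ``log2((KD + pc)/(control + pc))`` grouped by cluster.

    Returns ``(per_feature, summary)``; the summary carries size, median and
    quartiles per cluster, with NaN statistics for empty clusters.
    """
    kd, ctrl = kd.align(ctrl, join="inner")
    common = kd.index.intersection(clusters.table.index)
    ratio = np.log2((kd.loc[common] + pseudocount) / (ctrl.loc[common] + pseudocount))
    per_feature = pd.DataFrame(
        {"log2_kd_over_ctrl": ratio, "cluster": clusters.table.loc[common, "cluster"]}
    )
    rows = []
    for c in CLUSTERS:
        vals = per_feature.loc[per_feature["cluster"] == c, "log2_kd_over_ctrl"]
        if len(vals):
            rows.append(
                {
                    "cluster": c,
                    "n": len(vals),
                    "median": float(vals.median()),
                    "q1": float(vals.quantile(0.25)),
                    "q3": float(vals.quantile(0.75)),
                }
            )
        else:
            rows.append({"cluster": c, "n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan})
    summary = pd.DataFrame(rows).set_index("cluster")
    return per_feature, summary


# ---------------------------------------------------------------------------
# Fragment-level analyses
# ---------------------------------------------------------------------------


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Paired-end template intervals as a BED3(+name) table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rows.append(
                (parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else "")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    frags[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def intergenic_ratio(fragments: pd.DataFrame, intergenic: IntervalSet) -> float:
    """Fraction of templates falling *completely within* intergenic regions.

    A fragment counts as intergenic only when its whole template interval is
    contained in a single intergenic interval; any overlap with the excluded
    gene-proximal space disqualifies it.
    """
    if len(fragments) == 0:
        raise ValueError("no fragments supplied")
    n_in = 0
    for chrom, grp in fragments.groupby("chrom", sort=False):
        flags = intergenic.contains_many(
            str(chrom), grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        n_in += int(flags.sum())
    return n_in / len(fragments)


@dataclass
class DepositionProfile:
    """Scale-regions coverage metaprofile in RPKM.

    ``values`` holds ``flank_bins`` upstream bins at native scale, then
    ``body_bins`` bins over the rescaled gene body, then ``flank_bins``
    downstream bins.
    """

    values: np.ndarray
    flank_bp: int
    body_bins: int
    flank_bins: int
    n_genes: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 2 * self.flank_bins + self.body_bins:
            raise ValueError("profile length != 2*flank_bins + body_bins")

    def body(self) -> np.ndarray:
        return self.values[self.flank_bins : self.flank_bins + self.body_bins]

    def labels(self) -> list[str]:
        up = [f"u{i}" for i in range(self.flank_bins)]
        body = [f"b{i}" for i in range(self.body_bins)]
        down = [f"d{i}" for i in range(self.flank_bins)]
        return up + body + down

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"bin_index": np.arange(len(self.values)), "position_label": self.labels(),
             "mean_density": self.values}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _window_coverage(frags: pd.DataFrame, chrom: str, w0: int, w1: int) -> np.ndarray:
    """Per-base template coverage over ``[w0, w1)``; bases outside count 0."""
    depth = np.zeros(w1 - w0 + 1, dtype=np.int64)
    sub = frags[(frags["chrom"] == chrom) & (frags["start"] < w1) & (frags["end"] > w0)]
    if len(sub):
        s = np.clip(sub["start"].to_numpy() - w0, 0, w1 - w0)
        e = np.clip(sub["end"].to_numpy() - w0, 0, w1 - w0)
        np.add.at(depth, s, 1)
        np.add.at(depth, e, -1)
    return np.cumsum(depth)[:-1].astype(float)


def _block_sums(depth: np.ndarray, n_bins: int) -> tuple[np.ndarray, float]:
    """Integrated coverage over ``n_bins`` equal (possibly fractional) blocks."""
    cs = np.concatenate([[0.0], np.cumsum(depth)])
    edges = np.linspace(0.0, len(depth), n_bins + 1)
    integ = np.interp(edges, np.arange(len(cs)), cs)
    width = len(depth) / n_bins
    return np.diff(integ), width


def metaprofile(
    fragments: pd.DataFrame,
    genes: list[GenomicInterval],
    total_fragments: int,
    flank_bp: int = 2000,
    body_bins: int = 50,
    flank_bins: int = 20,
) -> DepositionProfile:
    """Mean scale-regions read-density profile over a gene set, in RPKM.

    Flanks are binned at native scale (``flank_bp / flank_bins`` bp per bin);
    each gene body is rescaled to ``body_bins`` blocks with fractional-base
    weighting. Per-bin density is
    ``coverage / (bin width in kb) / (total_fragments / 1e6)``, i.e. reads
    per kilobase per million mapped fragments, then averaged across genes.
    """
    if not genes:
        raise ValueError("no genes supplied")
    if total_fragments < len(fragments):
        raise ValueError("total_fragments must be >= number of fragments supplied")
    scale = 1.0 / (total_fragments / 1e6)
    profiles = []
    for g in genes:
        if len(g) < body_bins:
            logger.warning("gene %s shorter than body_bins; skipped", g.name or g)
            continue
        w0, w1 = g.start - flank_bp, g.end + flank_bp
        depth = _window_coverage(fragments, g.chrom, w0, w1)
        up = depth[:flank_bp]
        body = depth[flank_bp : flank_bp + len(g)]
        down = depth[flank_bp + len(g) :]
        vals = []
        for seg, nb in ((up, flank_bins), (body, body_bins), (down, flank_bins)):
            sums, width = _block_sums(seg, nb)
            vals.append(sums / (width / 1000.0) * scale)
        profiles.append(np.concatenate(vals))
    if not profiles:
        raise ValueError("no usable genes (all shorter than body_bins)")
    mean = np.mean(np.asarray(profiles), axis=0)
    return DepositionProfile(
        values=mean, flank_bp=flank_bp, body_bins=body_bins, flank_bins=flank_bins,
        n_genes=len(profiles),
    )


def gene_body_density(
    fragments: pd.DataFrame, genes: list[GenomicInterval], total_fragments: int
) -> pd.Series:
    """Mean gene-body read density per gene (RPKM), for correlation analyses."""
    # mean per-base depth over the body, scaled to reads/kb/million fragments
    scale = 1.0 / (total_fragments / 1e6)
    return pd.Series(
        {g.name: _window_coverage(fragments, g.chrom, g.start, g.end).mean() * 1000.0 * scale
         for g in genes},
        dtype=float,
    )


def spearman_deposition_vs_change(deposition: pd.Series, change: pd.Series) -> float:
    """Spearman rank correlation (average ranks for ties) of paired vectors."""
    deposition, change = deposition.align(change, join="inner")
    if len(deposition) < 3:
        raise ValueError("need at least 3 paired observations")
    if deposition.nunique() <= 1 or change.nunique() <= 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(deposition.to_numpy(), change.to_numpy())
    return float(rho)


# ---------------------------------------------------------------------------
# Count-table IO
# ---------------------------------------------------------------------------


def read_counts_table(path: str | Path, with_lengths: bool = True) -> ExpressionMatrix:
    """TSV with header ``feature_id  [length]  sample1 sample2 ...``."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    lengths = None
    if with_lengths:
        if "length" not in df.columns:
            raise ValueError(f"{path}: expected a 'length' column")
        lengths = df.pop("length").astype(float)
    elif "length" in df.columns:
        df = df.drop(columns=["length"])
    return ExpressionMatrix(data=df.astype(float), lengths=lengths, unit="counts")


def write_counts_table(em: ExpressionMatrix, path: str | Path) -> None:
    df = em.data.copy()
    if em.lengths is not None:
        df.insert(0, "length", em.lengths)
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")
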