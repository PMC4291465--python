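"""Lifespan and growth scoring of pooled mutants.

The statistic
-------------
For mutant *g* in sample *i*, the depth-normalized abundance is
``count_gi / depth_i``, and its fold-change versus the replicate's
reference sample (t = 0 wk for lifespan runs, t = 120 min for growth runs)
is

    fc_gi = (count_gi / depth_i) / (count_g0 / depth_0).

Each mutant carries up to two tags (uptag/downtag), each measured
independently. At timepoint *i* the two tag fold-changes are combined with
read-support weights

    w_up = (Up_i + Up_0) / (Up_i + Dn_i + Up_0 + Dn_0),   w_dn = 1 - w_up,

so the better-sequenced tag dominates; with a single valid tag its weight
is 1. A tag-timepoint with fewer than ``min_reads`` reads (default 10) is
excluded. The per-replicate statistic is the median of the combined
fold-changes over the non-reference timepoints, and the score is the mean
of the replicate medians. A score > 1 means the mutant became enriched in
the pool relative to the reference timepoint; long-lived calls use
score > 1.44 and short-lived/sick flags use score < 0.14, both strict.

By default the weights use raw read counts, exactly as the weighting
formula is written; ``normalized_weights=True`` computes them from
depth-normalized counts instead, which makes scores exactly invariant
under rescaling any single sample's counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from barseqcls.matching import CountMatrix, SampleMeta

NOT_SCORED = "not_scored"
LONG_LIVED = "long_lived"
SHORT_FLAG = "short_lived_flag"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and filters for screen scoring.

    min_reads: tag-timepoints with fewer raw reads are excluded (applies to
        the reference sample too; a tag with an under-covered reference is
        unusable in that replicate).
    long_lived_threshold / short_lived_threshold: strict score cutoffs for
        the long-lived call and the short-lived/sick flag.
    min_valid_timepoints: replicate contributes a median only if at least
        this many non-reference timepoints are valid.
    normalized_weights: compute tag weights from depth-normalized counts.
    """

    min_reads: int = 10
    long_lived_threshold: float = 1.44
    short_lived_threshold: float = 0.14
    min_valid_timepoints: int = 1
    normalized_weights: bool = False

    def __post_init__(self):
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.long_lived_threshold <= 0 or self.short_lived_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class WeightedFC:
    """Weighted combination of the two tag fold-changes at one timepoint."""

    w_up: float
    w_dn: float
    fc_combined: float
    valid: bool = True


def weighted_combine(
    up_i: float,
    dn_i: float,
    up_0: float,
    dn_0: float,
    fc_up: float | None,
    fc_dn: float | None,
) -> WeightedFC:
    """Combine tag fold-changes with read-support weights.

    ``fc_up``/``fc_dn`` are None when that tag is invalid at this
    timepoint. With both valid, w_up = (Up_i+Up_0)/(Up_i+Dn_i+Up_0+Dn_0);
    with one valid, its weight is 1; with neither, the result is invalid.
    """
    if fc_up is None and fc_dn is None:
        return WeightedFC(math.nan, math.nan, math.nan, valid=False)
    if fc_dn is None:
        return WeightedFC(1.0, 0.0, fc_up)
    if fc_up is None:
        return WeightedFC(0.0, 1.0, fc_dn)
    total = up_i + dn_i + up_0 + dn_0
    w_up = (up_i + up_0) / total
    return WeightedFC(w_up, 1.0 - w_up, w_up * fc_up + (1.0 - w_up) * fc_dn)


class BarSeqScreen:
    """One pooled screen (lifespan or growth) to be scored.

    Built from a :class:`CountMatrix` whose sample metadata marks exactly
    one ``role == "reference"`` sample per replicate; `fit()` computes
    fold-changes, tag weighting, per-replicate medians and calls, and
    returns a :class:`ScreenResults`.
    """

    def __init__(self, counts: CountMatrix, config: ScoringConfig | None = None):
        self.count_matrix = counts
        self.config = config or ScoringConfig()
        self.replicates = sorted({m.replicate for m in counts.samples})
        self._refs: dict[int, SampleMeta] = {}
        for rep in self.replicates:
            refs = [m for m in counts.samples if m.replicate == rep and m.role == "reference"]
            if len(refs) != 1:
                raise ValueError(
                    f"replicate {rep} must have exactly one reference sample, found {len(refs)}"
                )
            self._refs[rep] = refs[0]
            if counts.depth[refs[0].sample_id] <= 0:
                raise ValueError(f"reference sample {refs[0].sample_id} has zero depth")

    @classmethod
    def from_tables(
        cls,
        counts_tsv: str | Path,
        samples: list[SampleMeta],
        config: ScoringConfig | None = None,
    ) -> "BarSeqScreen":
        return cls(CountMatrix.from_tsv(counts_tsv, samples), config)

    # -- internals -----------------------------------------------------

    def _tag_frame(self, kind: str, genes: pd.Index) -> pd.DataFrame:
        cm = self.count_matrix
        if kind in cm.counts.index.get_level_values("tag_kind"):
            frame = cm.counts.xs(kind, level="tag_kind").astype(float)
        else:
            frame = pd.DataFrame(
                np.nan, index=pd.Index([], name="gene_id"), columns=cm.counts.columns
            )
        return frame.reindex(genes)  # NaN rows = tag not decoded for that gene

    def fold_changes(self) -> pd.DataFrame:
        """Per (gene, tag, replicate, timepoint) fold-changes with validity.

        Long-format frame with columns fc, valid, count, ref_count; the
        scoring path consumes the same quantities in wide form.
        """
        rows = []
        cm = self.count_matrix
        genes = cm.counts.index.get_level_values("gene_id").unique().sort_values()
        cfg = self.config
        for kind in ("up", "dn"):
            tag = self._tag_frame(kind, genes)
            for rep in self.replicates:
                ref = self._refs[rep]
                ref_counts = tag[ref.sample_id]
                ref_norm = ref_counts / cm.depth[ref.sample_id]
                for m in cm.samples:
                    if m.replicate != rep or m.role == "reference":
                        continue
                    c = tag[m.sample_id]
                    fc = (c / cm.depth[m.sample_id]) / ref_norm
                    valid = (
                        c.notna()
                        & (c >= cfg.min_reads)
                        & (ref_counts >= max(cfg.min_reads, 1))
                    )
                    block = pd.DataFrame(
                        {
                            "gene_id": genes,
                            "tag_kind": kind,
                            "replicate": rep,
                            "timepoint": m.timepoint,
                            "count": c.values,
                            "ref_count": ref_counts.values,
                            "fc": fc.values,
                            "valid": valid.values,
                        }
                    )
                    rows.append(block)
        return pd.concat(rows, ignore_index=True)

    def fit(self) -> "ScreenResults":
        cm = self.count_matrix
        cfg = self.config
        genes = cm.counts.index.get_level_values("gene_id").unique().sort_values()
        up = self._tag_frame("up", genes)
        dn = self._tag_frame("dn", genes)

        rep_medians: dict[int, pd.Series] = {}
        rep_nvalid: dict[int, pd.Series] = {}
        for rep in self.replicates:
            ref = self._refs[rep]
            sid0 = ref.sample_id
            d0 = cm.depth[sid0]
            aged = sorted(
                (m for m in cm.samples if m.replicate == rep and m.role != "reference"),
                key=lambda m: m.timepoint,
            )
            up0, dn0 = up[sid0], dn[sid0]
            ref_ok_up = up0 >= max(cfg.min_reads, 1)
            ref_ok_dn = dn0 >= max(cfg.min_reads, 1)
            combined = {}
            for m in aged:
                sid = m.sample_id
                di = cm.depth[sid]
                upi, dni = up[sid], dn[sid]
                fc_up = (upi / di) / (up0 / d0)
                fc_dn = (dni / di) / (dn0 / d0)
                vup = upi.notna() & (upi >= cfg.min_reads) & ref_ok_up.fillna(False)
                vdn = dni.notna() & (dni >= cfg.min_reads) & ref_ok_dn.fillna(False)
                if cfg.normalized_weights:
                    nup_i, ndn_i = upi / di, dni / di
                    nup_0, ndn_0 = up0 / d0, dn0 / d0
                    total = nup_i + ndn_i + nup_0 + ndn_0
                    w_up = (nup_i + nup_0) / total
                else:
                    total = upi + dni + up0 + dn0
                    w_up = (upi + up0) / total
                both = vup & vdn
                fc = pd.Series(np.nan, index=genes)
                fc[both] = w_up[both] * fc_up[both] + (1 - w_up[both]) * fc_dn[both]
                only_up = vup & ~vdn
                fc[only_up] = fc_up[only_up]
                only_dn = vdn & ~vup
                fc[only_dn] = fc_dn[only_dn]
                combined[m.timepoint] = fc
            fcs = pd.DataFrame(combined)
            n_valid = fcs.notna().sum(axis=1)
            median = fcs.median(axis=1, skipna=True)
            median[n_valid < cfg.min_valid_timepoints] = np.nan
            rep_medians[rep] = median
            rep_nvalid[rep] = n_valid

        med_frame = pd.DataFrame(rep_medians)
        score = med_frame.mean(axis=1, skipna=True)
        n_reps = med_frame.notna().sum(axis=1)

        call = pd.Series(INTERMEDIATE, index=genes)
        call[score > cfg.long_lived_threshold] = LONG_LIVED
        call[score < cfg.short_lived_threshold] = SHORT_FLAG
        call[n_reps == 0] = NOT_SCORED

        table = pd.DataFrame({"score": score, "call": call, "n_replicates": n_reps})
        for rep in self.replicates:
            table[f"median_rep{rep}"] = med_frame[rep]
            table[f"n_valid_rep{rep}"] = rep_nvalid[rep]
        table["single_replicate"] = (n_reps == 1) & (len(self.replicates) > 1)
        table.index.name = "gene_id"
        return ScreenResults(table=table, config=cfg)


@dataclass
class ScreenResults:
    """Fitted screen scores, per-replicate intermediates, and calls."""

    table: pd.DataFrame
    config: ScoringConfig

    @property
    def scores(self) -> pd.Series:
        """Scores of scorable genes only."""
        return self.table.loc[self.table["call"] != NOT_SCORED, "score"]

    @property
    def n_scored(self) -> int:
        return int((self.table["call"] != NOT_SCORED).sum())

    @property
    def long_lived(self) -> list[str]:
        """Genes with score strictly above the long-lived threshold, by descending score."""
        sub = self.table[self.table["call"] == LONG_LIVED]
        return list(sub.sort_values("score", ascending=False).index)

    @property
    def short_flagged(self) -> list[str]:
        sub = self.table[self.table["call"] == SHORT_FLAG]
        return list(sub.sort_values("score", ascending=False).index)

    def to_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, config: ScoringConfig | None = None) -> "ScreenResults":
        table = pd.read_csv(path, sep="\t", na_values="NA").set_index("gene_id")
        return cls(table=table, config=config or ScoringConfig())

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Bar-seq screen scoring",
            "=" * 52,
            f"genes in count matrix:      {len(self.table)}",
            f"genes scored:               {self.n_scored}",
            f"  single-replicate:         {int(self.table['single_replicate'].sum())}",
            f"long-lived (score > {cfg.long_lived_threshold:g}): {len(self.long_lived)}",
            f"short-lived flag (< {cfg.short_lived_threshold:g}): {len(self.short_flagged)}",
        ]
        if self.n_scored:
            s = self.scores
            lines.append(
                f"score median/IQR:           {s.median():.3f} "
                f"[{s.quantile(0.25):.3f}, {s.quantile(0.75):.3f}]"
            )
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Ordered-score plot: every scored gene ranked by score, long-lived
        genes highlighted; the standard overview figure for such screens."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.scores.sort_values(ascending=False).reset_index(drop=True)
        ax.plot(s.index, s.values, ".", ms=3, color="0.4")
        ll = s[s > self.config.long_lived_threshold]
        ax.plot(ll.index, ll.values, ".", ms=4, color="crimson")
        ax.axhline(self.config.long_lived_threshold, ls="--", lw=0.8, color="crimson")
        ax.set_xlabel("mutants ranked by score")
        ax.set_ylabel("score")
        return ax


# -- cross-screen operations -------------------------------------------


def compare_screens(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Overlap statistics between two hit sets (e.g. two screen variants)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    return {
        "overlap": len(a & b),
        "jaccard": len(a & b) / len(union) if union else math.nan,
        "unique_to_b": sorted(b - a),
    }


def correlate_scores(
    lifespan: ScreenResults | pd.Series,
    growth: ScreenResults | pd.Series,
    min_lifespan: float | None = None,
) -> tuple[int, float, float]:
    """Pearson correlation between lifespan and growth scores.

    Computed over genes scored in both screens, optionally restricted to
    lifespan score > ``min_lifespan``. Returns (n, r, two-sided p); p uses
    the t-approximation with n-2 degrees of freedom.
    """
    ls = lifespan.scores if isinstance(lifespan, ScreenResults) else lifespan.dropna()
    gs = growth.scores if isinstance(growth, ScreenResults) else growth.dropna()
    common = ls.index.intersection(gs.index)
    x, y = ls[common], gs[common]
    if min_lifespan is not None:
        keep = x > min_lifespan
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 genes scored in both screens, got {n}")
    r, p = stats.pearsonr(x, y)
    return n, float(r), float(p)


def enrichment(
    hits: Iterable[str], category: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """One-sided hypergeometric enrichment of a category among hits.

    Returns (upper-tail p for overlap >= observed, fold enrichment
    observed/expected).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    h, c = set(hits) & uni, set(category) & uni
    if set(hits) - uni or set(category) - uni:
        raise ValueError("hits and category must be subsets of the universe")
    k = len(h & c)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(c), len(h)))
    expected = len(h) * len(c) / len(uni)
    fold = k / expected if expected > 0 else math.nan
    return p, fold
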