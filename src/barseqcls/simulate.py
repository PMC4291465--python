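"""Ground-truthed simulator for pooled Bar-seq screens.

Emulates the statistical read-generating process of a pooled deletion
library: ~10^2–10^3 mutants with lognormal initial abundances, each with
an uptag and/or downtag; per-mutant weekly survival during quiescence (or
a per-hour doubling advantage during growth); relative pool composition
renormalized at every timepoint (Bar-seq measures composition, not
absolute viability); multinomial read sampling at fixed depth per sample;
a per-gene Beta-distributed up:dn read split; and iid per-base
substitution errors in emitted reads. Everything is driven by a single
seed and reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from barseqcls.tags import (
    DEFAULT_INDEXES,
    DEFAULT_PRIMERS,
    BarcodeDatabase,
    FLANK_LEN,
    TagRecord,
    build_database,
)
from barseqcls.matching import CountMatrix, SampleMeta

BASES = np.array(list("ACGT"))

# Timepoints of the two screen designs: weekly quiescence samples and an
# exponential-growth time course (reference first in both).
CLS_TIMEPOINTS_WK = (0.0, 4.0, 8.0, 12.0, 14.0)
GROWTH_TIMEPOINTS_MIN = (120.0, 230.0, 340.0, 460.0, 550.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated pooled screen.

    Tag-presence probabilities default to the decode-yield ratios of the
    real library (both/up-only/dn-only ≈ 1871/254/348 of 2473 genes).
    Survival is a mixture: bulk mutants draw weekly survival from
    Beta(8, 2) (mean 0.8/wk) and a ``long_lived_fraction`` survives
    perfectly (s = 1), giving the heavy top tail the long-lived calls
    target. Growth mode replaces survival with per-hour extra-doubling
    advantages ~ Normal(0, growth_advantage_sd).
    """

    n_genes: int = 1000
    p_both_tags: float = 0.757
    p_up_only: float = 0.103
    p_dn_only: float = 0.140
    abundance_mu: float = 0.0
    abundance_sigma: float = 0.5
    survival_alpha: float = 8.0
    survival_beta: float = 2.0
    long_lived_fraction: float = 0.05
    growth_advantage_sd: float = 0.1  # extra doublings per hour
    mode: str = "cls"  # "cls" | "growth"
    timepoints: tuple[float, ...] = CLS_TIMEPOINTS_WK
    unit: str = "weeks"
    n_replicates: int = 2
    depth: int = 1_000_000
    tag_bias_alpha: float = 10.0  # Beta(a, a): symmetric up:dn split
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.p_both_tags + self.p_up_only + self.p_dn_only > 1 + 1e-9:
            raise ValueError("tag-presence probabilities must sum to <= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.mode not in ("cls", "growth"):
            raise ValueError("mode must be 'cls' or 'growth'")

    def for_growth(self) -> "SimConfig":
        return replace(
            self, mode="growth", timepoints=GROWTH_TIMEPOINTS_MIN, unit="minutes"
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated pool.

    ``table``: per-gene tags present, initial proportion, weekly survival
    (or growth advantage), and expected pool proportion at each timepoint.
    """

    table: pd.DataFrame
    config: SimConfig

    @property
    def timepoint_columns(self) -> list[str]:
        return [f"prop_t{t:g}" for t in self.config.timepoints]

    def proportions(self, timepoint: float) -> pd.Series:
        return self.table[f"prop_t{timepoint:g}"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"gene{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_trajectories(cfg: SimConfig) -> SimTruth:
    """Draw per-gene ground truth and deterministic expected trajectories.

    CLS mode: proportion_g(t) = p_g(0) s_g^t / sum_h p_h(0) s_h^t with t in
    weeks. Growth mode: s_g^t is replaced by 2^(advantage_g * t/60) with t
    in minutes (advantage in extra doublings per hour).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)

    u = rng.random(cfg.n_genes)
    has_up = (u < cfg.p_both_tags) | (
        (u >= cfg.p_both_tags) & (u < cfg.p_both_tags + cfg.p_up_only)
    )
    has_dn = (u < cfg.p_both_tags) | (u >= cfg.p_both_tags + cfg.p_up_only)

    p0 = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, cfg.n_genes)
    p0 /= p0.sum()

    if cfg.mode == "cls":
        s = rng.beta(cfg.survival_alpha, cfg.survival_beta, cfg.n_genes)
        long_lived = rng.random(cfg.n_genes) < cfg.long_lived_fraction
        s[long_lived] = 1.0
        rate_col = "survival_per_week"
    else:
        s = rng.normal(0.0, cfg.growth_advantage_sd, cfg.n_genes)
        long_lived = np.zeros(cfg.n_genes, dtype=bool)
        rate_col = "growth_advantage_per_hr"

    split = rng.beta(cfg.tag_bias_alpha, cfg.tag_bias_alpha, cfg.n_genes)

    table = pd.DataFrame(
        {
            "has_up": has_up,
            "has_dn": has_dn,
            "initial_proportion": p0,
            rate_col: s,
            "is_long_lived_truth": long_lived,
            "up_fraction": split,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    t_ref = cfg.timepoints[0]
    for t in cfg.timepoints:
        if cfg.mode == "cls":
            weight = p0 * np.power(s, t - t_ref)
        else:
            weight = p0 * np.power(2.0, s * (t - t_ref) / 60.0)
        table[f"prop_t{t:g}"] = weight / weight.sum()
    return SimTruth(table=table, config=cfg)


def truth_sample_sheet(cfg: SimConfig) -> list[SampleMeta]:
    """Sample sheet matching the simulated design: one reference plus aged
    timepoints per replicate, indexes assigned cyclically."""
    metas = []
    t_ref = cfg.timepoints[0]
    n_idx = len(DEFAULT_INDEXES)
    i = 0
    for rep in range(1, cfg.n_replicates + 1):
        for t in cfg.timepoints:
            metas.append(
                SampleMeta(
                    sample_id=f"rep{rep}_t{t:g}",
                    replicate=rep,
                    timepoint=t,
                    unit=cfg.unit,
                    role="reference" if t == t_ref else "aged",
                    index_id=(i % n_idx) + 1,
                )
            )
            i += 1
    return metas


def sample_counts(truth: SimTruth, cfg: SimConfig | None = None,
                  seed: int | None = None) -> CountMatrix:
    """Multinomial read sampling at the configured depth for every sample.

    Each sample's reads are distributed over (gene, tag) cells with
    probabilities = pool proportions times the gene's up:dn split (all
    mass on the present tag for single-tag genes). Per-sample counts sum
    exactly to the depth.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    samples = truth_sample_sheet(cfg)
    genes = truth.table.index
    has_up = truth.table["has_up"].to_numpy()
    has_dn = truth.table["has_dn"].to_numpy()
    split = truth.table["up_fraction"].to_numpy()
    up_frac = np.where(has_up & has_dn, split, np.where(has_up, 1.0, 0.0))

    index = pd.MultiIndex.from_tuples(
        [(g, k) for g in genes for k in ("up", "dn")], names=["gene_id", "tag_kind"]
    )
    data = {}
    for m in samples:
        props = truth.proportions(m.timepoint).to_numpy()
        p_up = props * up_frac
        p_dn = props * (1.0 - up_frac)
        p = np.column_stack([p_up, p_dn]).ravel()
        p = p / p.sum()
        data[m.sample_id] = rng.multinomial(cfg.depth, p) if cfg.depth > 0 else np.zeros(len(p), dtype=int)
    counts = pd.DataFrame(data, index=index, dtype=int)
    # drop structurally absent tags (gene lacks that barcode entirely)
    present = pd.Series(
        np.column_stack([has_up, has_dn]).ravel(), index=index
    )
    counts = counts[present.to_numpy()]
    return CountMatrix(counts=counts, samples=samples)


def truth_tags(truth: SimTruth, seed: int | None = None) -> list[TagRecord]:
    """Random 20-mer barcodes (and 33-nt flanks) for every simulated tag."""
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    records = []
    seen: set[str] = set()

    def fresh(length: int) -> str:
        while True:
            s = "".join(rng.choice(BASES, size=length))
            if s not in seen:
                seen.add(s)
                return s

    for gene_id, row in truth.table.iterrows():
        for kind, present in (("up", row["has_up"]), ("dn", row["has_dn"])):
            if present:
                records.append(
                    TagRecord(
                        gene_id=gene_id,
                        tag_kind=kind,
                        tag_seq=fresh(20),
                        expected_flank=fresh(FLANK_LEN),
                    )
                )
    return records


def truth_database(truth: SimTruth, tags: list[TagRecord] | None = None,
                   indexes: Sequence[str] = DEFAULT_INDEXES) -> BarcodeDatabase:
    return build_database(tags or truth_tags(truth), indexes, DEFAULT_PRIMERS)


def _mutate(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply iid substitutions to a (n_reads, read_len) byte matrix of bases."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n = int(mask.sum())
    if n:
        # substitute with one of the three other bases, uniformly
        current = reads[mask]
        offsets = rng.integers(1, 4, size=n)
        idx = np.searchsorted(_BASE_BYTES, current)
        reads[mask] = _BASE_BYTES[(idx + offsets) % 4]
    return reads


_BASE_BYTES = np.sort(np.frombuffer(b"ACGT", dtype=np.uint8))


def _write_fastq(path: Path, seqs: list[str], prefix: str) -> None:
    qual_cache: dict[int, str] = {}
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            q = qual_cache.setdefault(len(s), "I" * len(s))
            fh.write(f"@{prefix}_{i}\n{s}\n+\n{q}\n")


def emit_fastq(
    counts: CountMatrix,
    db: BarcodeDatabase,
    cfg: SimConfig,
    out_dir: str | Path,
    read_len: int = 50,
) -> dict[str, Path]:
    """Write one 50-nt FASTQ per sample realizing the given counts.

    Each counted read is the sample's database entry (that gene/tag at the
    sample's multiplex index) truncated to ``read_len``, with iid
    substitutions at ``cfg.error_rate``. Read order is shuffled
    deterministically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 3)
    entry_by_key = {(e.gene_id, e.tag_kind, e.index_id): e.seq for e in db.entries}
    paths = {}
    for m in counts.samples:
        col = counts.counts[m.sample_id]
        seq_list = []
        for (gene_id, tag_kind), n in col.items():
            if n == 0:
                continue
            key = (gene_id, tag_kind, m.index_id)
            if key not in entry_by_key:
                raise KeyError(f"no database entry for {key}")
            seq_list.append((entry_by_key[key][:read_len], int(n)))
        total = sum(n for _, n in seq_list)
        mat = np.empty((total, read_len), dtype=np.uint8)
        pos = 0
        for seq, n in seq_list:
            mat[pos : pos + n] = np.frombuffer(seq.encode(), dtype=np.uint8)
            pos += n
        mat = _mutate(mat, cfg.error_rate, rng)
        order = rng.permutation(total)
        seqs = [mat[i].tobytes().decode() for i in order]
        path = out_dir / f"{m.sample_id}.fastq"
        _write_fastq(path, seqs, m.sample_id)
        paths[m.sample_id] = path
    return paths


def emit_decode_fastq(
    tags: Sequence[TagRecord],
    cfg: SimConfig,
    path: str | Path,
    reads_per_tag: int = 20,
    index: str = DEFAULT_INDEXES[0],
    spacer: str | None = None,
) -> Path:
    """Write a 101-nt decode-run FASTQ with ``reads_per_tag`` reads per tag.

    Read anatomy: 4-nt index + 18-nt primer + 20-nt barcode + 26-nt spacer
    + 33-nt genomic flank, with iid substitutions at ``cfg.error_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    if spacer is None:
        spacer = "ACGT" * 7
        spacer = spacer[:26]
    seqs = []
    for t in tags:
        if t.expected_flank is None:
            raise ValueError(f"tag {t.gene_id}/{t.tag_kind} lacks an expected flank")
        primer = DEFAULT_PRIMERS.forward(t.tag_kind)
        template = index + primer + t.tag_seq + spacer + t.expected_flank
        for _ in range(reads_per_tag):
            seqs.append(template)
    if seqs:
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1).copy()
        mat = _mutate(mat, cfg.error_rate, rng)
        order = rng.permutation(len(seqs))
        seqs = [mat[i].tobytes().decode() for i in order]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_fastq(path, seqs, "decode")
    return path
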