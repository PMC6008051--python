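"""Synthetic multi-tissue muscle RNA-seq datasets with planted truth.

The generator emulates the statistical structure the downstream
analysis assumes:

* negative-binomial read counts (variance = m + phi·m²) over log-normal
  per-tissue expression means, at a configurable nominal depth;
* three muscle classes (skeletal / cardiac / smooth) separated by
  per-transcript class-level shifts;
* a latent per-tissue ``fast_fraction`` in [0, 1] standing in for
  fast-twitch fiber content: it partitions reads among *Myh*-like
  myosin heavy-chain genes (MYH7 slow; MYH2/MYH1/MYH4 fast) and drives
  designated axis-driver genes whose noise is calibrated to hit target
  R² values against the axis in expectation;
* a planted fraction of differentially expressed transcripts, shifted
  by ±log2(fold change) in random non-trivial tissue subsets;
* mitochondrial transcripts scaled so each tissue's mitochondrial read
  share lands in a configured range;
* optionally, sex-biased transcripts shifted in male samples.

Every random choice flows from ``SimConfig.seed``: the same config
produces byte-identical output. Planted truth is returned as a
:class:`SimTruth` whose fields are all recomputable from the emitted
dataset plus the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DataModelError,
    ExpressionDataset,
    JunctionRecord,
    JunctionSet,
    OrthologTable,
)

# Pools of tissue names by muscle class. The skeletal pool is ordered to
# cover the classic slow->fast spectrum via DEFAULT_FAST_FRACTIONS.
SKELETAL_POOL = ["SOL", "DIA", "TON", "MAS", "FDB", "EYE", "GAS", "PLA", "QUAD", "TA", "EDL"]
CARDIAC_POOL = ["left_ventricle", "right_ventricle", "atria"]
SMOOTH_POOL = ["aorta", "bladder", "esophagus", "uterus"]

# Latent fast-twitch content per named skeletal muscle: soleus nearly
# pure slow, EDL/TA nearly pure fast, mixed muscles in between.
DEFAULT_FAST_FRACTIONS = {
    "SOL": 0.03, "DIA": 0.35, "TON": 0.45, "MAS": 0.50, "FDB": 0.55,
    "EYE": 0.60, "GAS": 0.75, "PLA": 0.80, "QUAD": 0.85, "TA": 0.90, "EDL": 0.92,
}

MYH_GENES = ("MYH7", "MYH2", "MYH1", "MYH4")  # slow, fast-IIa, fast-IIx, fast-IIb
FAST_MYH_WEIGHTS = {"MYH2": 0.25, "MYH1": 0.30, "MYH4": 0.45}
# Overall Myh transcriptional output scales with how striated the tissue is.
MYH_CLASS_SCALE = {"skeletal": 1.0, "cardiac": 0.05, "smooth": 0.01}


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Expression means are in FPKM-like units: the expected count for
    transcript i in sample j is mu_it · length_kb_i · depth_j / 10^6.
    """

    n_transcripts: int = 2000
    tissues_per_class: dict = field(
        default_factory=lambda: {"skeletal": 11, "cardiac": 2, "smooth": 3}
    )
    n_replicates: int = 6
    depth_mean: float = 2e6
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_fold_change: float = 4.0
    de_min_baseline_fpkm: float = 4.0
    mito_fraction_range: tuple[float, float] = (0.05, 0.35)
    n_mito_transcripts: int = 13  # the mtDNA protein-coding mRNA complement
    n_axis_drivers: int = 30
    axis_r2_targets: tuple[float, ...] = (0.95,)
    axis_amplitude: float = 4.0
    # mean log2 expression of axis drivers at fast_fraction 0; None means
    # baseline_log2_mean + 1. Raise it when the driver slope is steep so
    # driver expression stays above the log2(FPKM+1) saturation region.
    axis_intercept_log2: float | None = None
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    class_shift_sd: float = 0.7
    tissue_shift_sd: float = 0.15
    myh_total_fpkm: float = 3000.0
    sex_de_fraction: float = 0.0
    sex_de_fold_change: float = 2.0
    up_in_male_fraction: float = 0.8
    species: str = "mouse"
    fast_fractions: dict | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataModelError("SimConfig.seed is mandatory")
        for name in ("de_fraction", "sex_de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataModelError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise DataModelError(f"invalid mito_fraction_range {self.mito_fraction_range}")
        if self.depth_mean <= 0:
            raise DataModelError("depth_mean must be positive")
        if self.nb_dispersion < 0:
            raise DataModelError("nb_dispersion must be >= 0")
        n_special = (
            self.n_mito_transcripts
            + self.n_axis_drivers
            + len(MYH_GENES)
            + int(round(self.de_fraction * self.n_transcripts))
        )
        if n_special > self.n_transcripts:
            raise DataModelError(
                f"DE fraction plus driver/Myh/mito assignments ({n_special}) "
                f"exceed n_transcripts ({self.n_transcripts})"
            )

    @property
    def n_tissues(self) -> int:
        return sum(self.tissues_per_class.values())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "mito_fraction_range" in raw:
            raw["mito_fraction_range"] = tuple(raw["mito_fraction_range"])
        if "axis_r2_targets" in raw:
            raw["axis_r2_targets"] = tuple(raw["axis_r2_targets"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Planted ground truth for a simulated dataset.

    ``de_direction`` maps transcript_id -> {tissue: ±1} for the shifted
    tissues. ``mu_fpkm`` holds the exact per-tissue expression means, so
    every analytic expectation (including expected counts) is
    recomputable from truth + config.
    """

    de_transcripts: set[str] = field(default_factory=set)
    de_direction: dict[str, dict[str, int]] = field(default_factory=dict)
    axis_drivers: dict[str, float] = field(default_factory=dict)
    latent_fast_fraction: dict[str, float] = field(default_factory=dict)
    mito_transcripts: set[str] = field(default_factory=set)
    mito_share: dict[str, float] = field(default_factory=dict)
    sex_de_transcripts: set[str] = field(default_factory=set)
    sex_de_up_in_male: set[str] = field(default_factory=set)
    novel_junctions: dict[tuple, str] = field(default_factory=dict)
    concordant_direction_fraction: float | None = None
    concordance_same_direction: set[str] = field(default_factory=set)
    mu_fpkm: pd.DataFrame | None = None
    depth_per_sample: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        """Flat machine-readable sidecar (documented schema)."""
        payload = {
            "de_transcripts": sorted(self.de_transcripts),
            "de_direction": {t: d for t, d in sorted(self.de_direction.items())},
            "axis_drivers": dict(sorted(self.axis_drivers.items())),
            "latent_fast_fraction": self.latent_fast_fraction,
            "mito_transcripts": sorted(self.mito_transcripts),
            "mito_share": self.mito_share,
            "sex_de_transcripts": sorted(self.sex_de_transcripts),
            "sex_de_up_in_male": sorted(self.sex_de_up_in_male),
            "novel_junctions": {
                f"{k[0]}:{k[1]}-{k[2]}:{k[3]}": v for k, v in sorted(self.novel_junctions.items())
            },
            "concordant_direction_fraction": self.concordant_direction_fraction,
            "concordance_same_direction": sorted(self.concordance_same_direction),
            "depth_per_sample": self.depth_per_sample,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _tissue_layout(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    """Assign tissue names per class from the name pools."""
    pools = {"skeletal": SKELETAL_POOL, "cardiac": CARDIAC_POOL, "smooth": SMOOTH_POOL}
    tissues: list[str] = []
    classes: dict[str, str] = {}
    for cls in ("skeletal", "cardiac", "smooth"):
        n = int(config.tissues_per_class.get(cls, 0))
        pool = pools[cls]
        for i in range(n):
            name = pool[i] if i < len(pool) else f"{cls}_{i + 1:02d}"
            tissues.append(name)
            classes[name] = cls
    return tissues, classes


def _fast_fractions(config: SimConfig, tissues: list[str], classes: dict[str, str],
                    rng: np.random.Generator) -> dict[str, float]:
    out: dict[str, float] = {}
    override = config.fast_fractions or {}
    for t in tissues:
        if t in override:
            out[t] = float(override[t])
        elif classes[t] != "skeletal":
            out[t] = 0.0
        elif t in DEFAULT_FAST_FRACTIONS:
            out[t] = DEFAULT_FAST_FRACTIONS[t]
        else:
            out[t] = float(rng.uniform(0.05, 0.95))
    return out


def _make_annotation(config: SimConfig, rng: np.random.Generator,
                     prefix: str = "T") -> pd.DataFrame:
    """Transcript annotation with exon structures on a synthetic genome.

    Transcripts are laid out on non-overlapping genomic blocks so that
    simulated junctions never collide across genes.
    """
    n = config.n_transcripts
    ids = [f"{prefix}{i:05d}" for i in range(n)]
    n_mito = config.n_mito_transcripts
    mito_idx = set(range(n - n_mito, n))  # last block is chrM

    lengths = np.clip(
        np.round(rng.lognormal(mean=np.log(1800), sigma=0.6, size=n)).astype(int), 200, 20000
    )
    gene_symbols = [f"GENE{i:05d}" for i in range(n)]

    rows = []
    cursor = {c: 10_000 for c in [f"chr{k}" for k in range(1, 20)]}
    chrom_cycle = [f"chr{k}" for k in range(1, 20)]
    mito_cursor = 100
    for i, tid in enumerate(ids):
        L = int(lengths[i])
        if i in mito_idx:
            chrom, strand = "chrM", "+"
            exons = ((mito_cursor, mito_cursor + L),)
            mito_cursor += L + 100
        else:
            chrom = chrom_cycle[i % len(chrom_cycle)]
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 9))
            cuts = np.sort(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False)) \
                if n_exons > 1 else np.array([], dtype=int)
            exon_lens = np.diff(np.concatenate(([0], cuts, [L])))
            exon_lens = np.maximum(exon_lens, 1)
            exon_lens[-1] = L - exon_lens[:-1].sum()
            if exon_lens[-1] < 1:  # rare: re-spread evenly
                exon_lens = np.full(n_exons, L // n_exons)
                exon_lens[-1] = L - exon_lens[:-1].sum()
            start = cursor[chrom]
            exons = []
            pos = start
            for el in exon_lens:
                exons.append((pos, pos + int(el)))
                pos += int(el) + int(rng.integers(200, 2000))  # intron gap
            exons = tuple(exons)
            cursor[chrom] = pos + 5000
        rows.append(
            dict(transcript_id=tid, gene_symbol=gene_symbols[i], chrom=chrom,
                 is_mitochondrial=(i in mito_idx), length_bp=L, strand=strand, exons=exons)
        )
    ann = pd.DataFrame(rows).set_index("transcript_id")
    return ann


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial via Gamma-Poisson mixture; Poisson when phi == 0."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=np.maximum(mean, 1e-300) * phi)
    lam[mean <= 0] = 0.0
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[ExpressionDataset, SimTruth]:
    """Draw a full ExpressionDataset plus planted truth from the config."""
    rng = np.random.default_rng(config.seed)
    tissues, classes = _tissue_layout(config)
    fast = _fast_fractions(config, tissues, classes, rng)
    n, T = config.n_transcripts, len(tissues)

    ann = _make_annotation(config, rng)
    ids = list(ann.index)
    mito_ids = list(ann.index[ann["is_mitochondrial"]])

    # --- role assignment over nuclear transcripts --------------------------
    nuclear_ids = [t for t in ids if t not in set(mito_ids)]
    myh_ids = nuclear_ids[: len(MYH_GENES)]
    ann.loc[myh_ids, "gene_symbol"] = list(MYH_GENES)
    remaining = nuclear_ids[len(MYH_GENES):]

    driver_ids = list(rng.choice(remaining, size=config.n_axis_drivers, replace=False)) \
        if config.n_axis_drivers else []
    remaining2 = [t for t in remaining if t not in set(driver_ids)]

    # --- baseline expression (FPKM-like units) ------------------------------
    base_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    log2_mu = np.tile(base_log2[:, None], (1, T))  # transcripts × tissues

    pos = {t: k for k, t in enumerate(ids)}
    tix = {t: k for k, t in enumerate(tissues)}

    # class-level shifts give the smooth/cardiac/skeletal cluster structure
    if config.class_shift_sd > 0:
        class_eff = {c: rng.normal(0.0, config.class_shift_sd, size=n)
                     for c in ("skeletal", "cardiac", "smooth")}
        for t in tissues:
            log2_mu[:, tix[t]] += class_eff[classes[t]]
    # small per-tissue idiosyncratic effects
    if config.tissue_shift_sd > 0:
        for t in tissues:
            log2_mu[:, tix[t]] += rng.normal(0.0, config.tissue_shift_sd, size=n)

    truth = SimTruth(latent_fast_fraction=dict(fast))

    # --- axis drivers: log2 mu = a + b·fast_fraction + calibrated noise -----
    fvec = np.array([fast[t] for t in tissues])
    sd_f = fvec.std(ddof=0)
    targets = list(config.axis_r2_targets) or [0.95]
    for k, tid in enumerate(driver_ids):
        r2 = float(targets[k % len(targets)])
        b = config.axis_amplitude * (1 if rng.random() < 0.5 else -1)
        intercept = (config.axis_intercept_log2 if config.axis_intercept_log2 is not None
                     else config.baseline_log2_mean + 1.0)
        a = float(rng.normal(intercept, 0.5))
        noise_sd = 0.0 if r2 >= 1.0 else abs(b) * sd_f * np.sqrt((1.0 - r2) / r2)
        prof = a + b * fvec + rng.normal(0.0, noise_sd, size=T)
        log2_mu[pos[tid], :] = prof
        truth.axis_drivers[tid] = r2

    # --- Myh partition by fast_fraction -------------------------------------
    for t in tissues:
        total = config.myh_total_fpkm * MYH_CLASS_SCALE[classes[t]]
        f = fast[t]
        shares = {"MYH7": (1.0 - f)}
        shares.update({g: f * w for g, w in FAST_MYH_WEIGHTS.items()})
        for tid, gene in zip(myh_ids, MYH_GENES):
            log2_mu[pos[tid], tix[t]] = np.log2(max(total * shares[gene], 2 ** -10))

    # --- planted DE ----------------------------------------------------------
    n_de = int(round(config.de_fraction * n))
    if n_de:
        base_fpkm = 2.0 ** base_log2
        eligible = [t for t in remaining2 if base_fpkm[pos[t]] >= config.de_min_baseline_fpkm]
        if len(eligible) < n_de:
            raise DataModelError(
                f"only {len(eligible)} transcripts eligible for DE planting, need {n_de}"
            )
        de_ids = list(rng.choice(eligible, size=n_de, replace=False))
        shift = np.log2(config.de_fold_change)
        for tid in de_ids:
            size = int(rng.integers(1, T))  # non-trivial subset: 1..T-1
            subset = list(rng.choice(tissues, size=size, replace=False))
            direction = 1 if rng.random() < 0.5 else -1
            for t in subset:
                log2_mu[pos[tid], tix[t]] += direction * shift
            truth.de_direction[tid] = {t: direction for t in subset}
        truth.de_transcripts = set(de_ids)

    # --- mitochondrial load --------------------------------------------------
    mu = 2.0 ** log2_mu
    len_kb = ann["length_bp"].to_numpy() / 1000.0
    mito_mask = ann["is_mitochondrial"].to_numpy()
    lo, hi = config.mito_fraction_range
    for t in tissues:
        share = float(rng.uniform(lo, hi))
        col = mu[:, tix[t]]
        nuclear_reads = float((col[~mito_mask] * len_kb[~mito_mask]).sum())
        mito_reads = float((col[mito_mask] * len_kb[mito_mask]).sum())
        target = share / (1.0 - share) * nuclear_reads
        if mito_reads > 0:
            mu[mito_mask, tix[t]] *= target / mito_reads
        truth.mito_share[t] = share
    truth.mito_transcripts = set(mito_ids)

    # --- sample table --------------------------------------------------------
    sample_rows = []
    for t in tissues:
        for r in range(1, config.n_replicates + 1):
            sex = "male" if r <= (config.n_replicates + 1) // 2 else "female"
            sample_rows.append(
                dict(sample_id=f"{t}_r{r}", tissue=t, muscle_class=classes[t],
                     species=config.species, sex=sex, replicate=r)
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # --- optional sex-biased expression --------------------------------------
    n_sex = int(round(config.sex_de_fraction * n))
    sex_mult = np.ones((n, len(samples)))
    if n_sex:
        candidates = [t for t in remaining2 if t not in truth.de_transcripts
                      and 2.0 ** base_log2[pos[t]] >= config.de_min_baseline_fpkm]
        sex_ids = list(rng.choice(candidates, size=n_sex, replace=False))
        male_cols = (samples["sex"] == "male").to_numpy()
        shift = config.sex_de_fold_change
        for tid in sex_ids:
            up_male = rng.random() < config.up_in_male_fraction
            factor = shift if up_male else 1.0 / shift
            sex_mult[pos[tid], male_cols] = factor
            if up_male:
                truth.sex_de_up_in_male.add(tid)
        truth.sex_de_transcripts = set(sex_ids)

    # --- draw counts ---------------------------------------------------------
    depth = np.full(len(samples), float(config.depth_mean))
    tissue_col = [tix[t] for t in samples["tissue"]]
    mean_mat = (mu[:, tissue_col] * sex_mult) * len_kb[:, None] * (depth[None, :] / 1e6)
    counts = _nb_draw(rng, mean_mat, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=ids, columns=samples.index, dtype=np.int64)
    dataset = ExpressionDataset(counts=counts_df, samples=samples, transcripts=ann)

    truth.mu_fpkm = pd.DataFrame(mu, index=ids, columns=tissues)
    truth.depth_per_sample = {s: float(d) for s, d in zip(samples.index, depth)}
    return dataset, truth


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def simulate_junctions(
    annotation: pd.DataFrame,
    n_novel: int,
    reads_range: tuple[int, int] = (1, 200),
    seed: int | None = None,
    sample_ids: Sequence[str] = ("pooled",),
) -> tuple[JunctionSet, SimTruth]:
    """Emit all annotated introns with random support plus planted novel ones.

    Novel junctions alternate between two classes: ``exon_skipping``
    (both ends on annotated exon boundaries of non-adjacent exons) and
    ``novel_exon_or_site`` (at least one end off any annotated boundary,
    placed 37 bp inside an annotated intron).
    """
    if seed is None:
        raise DataModelError("seed is mandatory")
    rng = np.random.default_rng(seed)
    lo, hi = reads_range

    from .junction_discovery import known_intron_set

    known = known_intron_set(annotation)

    # candidate novel sites, deterministic order over sorted transcripts
    skip_candidates = []   # (chrom, start, end, strand)
    site_candidates = []
    boundary_keys = set()
    for tid in sorted(annotation.index):
        row = annotation.loc[tid]
        exons = row["exons"]
        if len(exons) >= 2:
            for k in range(len(exons) - 2):
                cand = (row["chrom"], exons[k][1], exons[k + 2][0], row["strand"])
                skip_candidates.append(cand)
            for k in range(len(exons) - 1):
                a, b = exons[k][1], exons[k + 1][0]
                if b - a >= 80:
                    site_candidates.append((row["chrom"], a, b - 37, row["strand"]))
    skip_candidates = [c for c in skip_candidates if c not in known]
    site_candidates = [c for c in site_candidates if c not in known]

    n_skip = n_novel // 2
    n_site = n_novel - n_skip
    if n_skip > len(skip_candidates) or n_site > len(site_candidates):
        raise DataModelError(
            f"cannot construct {n_novel} novel junctions "
            f"({len(skip_candidates)} skipping / {len(site_candidates)} novel-site sites available)"
        )
    skip_pick = [skip_candidates[i] for i in
                 rng.choice(len(skip_candidates), size=n_skip, replace=False)] if n_skip else []
    # avoid colliding with picked skip junctions
    taken = set(skip_pick)
    site_pool = [c for c in site_candidates if c not in taken]
    site_pick = [site_pool[i] for i in
                 rng.choice(len(site_pool), size=n_site, replace=False)] if n_site else []

    truth = SimTruth()
    for key in skip_pick:
        truth.novel_junctions[key] = "exon_skipping"
    for key in site_pick:
        truth.novel_junctions[key] = "novel_exon_or_site"

    records = []
    all_keys = sorted(known) + skip_pick + site_pick
    for key in all_keys:
        chrom, start, end, strand = key
        for sid in sample_ids:
            records.append(JunctionRecord(
                chrom=chrom, intron_start=int(start), intron_end=int(end), strand=strand,
                read_count=int(rng.integers(lo, hi + 1)), sample_id=str(sid),
            ))
    return JunctionSet(records=records, dialect="zero_half_open"), truth


# ---------------------------------------------------------------------------
# two-species pair
# ---------------------------------------------------------------------------

def simulate_species_pair(
    config: SimConfig,
    concordance: float,
    seed: int | None = None,
    n_shared_de: int = 200,
    n_private_de: int = 25,
    between_species_sd: float = 1.45,
    shared_de_fold_change: float = 16.0,
) -> tuple[ExpressionDataset, ExpressionDataset, OrthologTable, SimTruth]:
    """Two 2-tissue (EDL-like / soleus-like) datasets with planted concordance.

    Among the ``n_shared_de`` orthologs planted DE in both species, a
    deterministic quota of exactly ``round(concordance * n_shared_de)``
    shares the sign of its log fold change between species; the rest
    have the sign flipped in species B. Each species additionally gets
    ``n_private_de`` transcripts DE only in that species.
    """
    if not 0.0 <= concordance <= 1.0:
        raise DataModelError(f"concordance must be in [0, 1], got {concordance}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n = config.n_transcripts
    tissues = ["EDL", "soleus"]
    shift = np.log2(shared_de_fold_change) / 2.0  # ± half-shift per tissue

    # shared ortholog backbone
    base_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    # mito rows (the trailing n_mito indices in the annotation layout) are
    # rescaled to a per-species load later, so DE is never planted on them
    nuclear = np.arange(n) < n - config.n_mito_transcripts
    eligible = np.flatnonzero(
        (2.0 ** base_log2 >= max(config.de_min_baseline_fpkm, 8.0)) & nuclear
    )
    need = n_shared_de + 2 * n_private_de
    if len(eligible) < need:
        raise DataModelError(f"only {len(eligible)} eligible transcripts, need {need}")
    picked = rng.choice(eligible, size=need, replace=False)
    shared_idx = picked[:n_shared_de]
    privA_idx = picked[n_shared_de:n_shared_de + n_private_de]
    privB_idx = picked[n_shared_de + n_private_de:]

    n_same = int(round(concordance * n_shared_de))
    order = rng.permutation(n_shared_de)
    same_set = set(shared_idx[order[:n_same]])

    def build(species: str, prefix: str, flip: bool) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            n_transcripts=n, tissues_per_class={"skeletal": 2, "cardiac": 0, "smooth": 0},
            n_replicates=config.n_replicates, depth_mean=config.depth_mean,
            nb_dispersion=config.nb_dispersion, de_fraction=0.0, n_axis_drivers=0,
            class_shift_sd=0.0, tissue_shift_sd=0.0,
            n_mito_transcripts=config.n_mito_transcripts,
            mito_fraction_range=config.mito_fraction_range,
            species=species, seed=int(sub_rng.integers(0, 2**31 - 1)),
            fast_fractions={"EDL": 0.92, "SOL": 0.03},
        )
        ann = _make_annotation(cfg, sub_rng, prefix=prefix)
        mito_mask = ann["is_mitochondrial"].to_numpy()
        log2_mu = np.tile(base_log2[:, None], (1, 2)).copy()
        # species-level divergence shared across both tissues of this species;
        # each species drifts sd/sqrt(2) from the common ancestor so the total
        # A-vs-B divergence SD is between_species_sd
        log2_mu += sub_rng.normal(0.0, between_species_sd / np.sqrt(2.0), size=n)[:, None]

        signA = {}
        for i in shared_idx:
            s = 1 if (i % 2 == 0) else -1  # deterministic base sign per gene
            signA[i] = s
            sB = s if (not flip or i in same_set) else -s
            use = sB if flip else s
            log2_mu[i, 0] += use * shift   # EDL
            log2_mu[i, 1] -= use * shift   # soleus
        priv = privB_idx if flip else privA_idx
        for i in priv:
            s = 1 if sub_rng.random() < 0.5 else -1
            log2_mu[i, 0] += s * shift
            log2_mu[i, 1] -= s * shift

        mu = 2.0 ** log2_mu
        len_kb = ann["length_bp"].to_numpy() / 1000.0
        lo, hi = cfg.mito_fraction_range
        # one mitochondrial load per species, shared by both tissues: the
        # planted ortholog contrast stays the only between-tissue signal
        share = float(sub_rng.uniform(lo, hi))
        for j in range(2):
            col = mu[:, j]
            nuclear = float((col[~mito_mask] * len_kb[~mito_mask]).sum())
            mito = float((col[mito_mask] * len_kb[mito_mask]).sum())
            if mito > 0:
                mu[mito_mask, j] *= (share / (1 - share)) * nuclear / mito
        rows = []
        for j, t in enumerate(tissues):
            for r in range(1, cfg.n_replicates + 1):
                sex = "male" if r <= (cfg.n_replicates + 1) // 2 else "female"
                rows.append(dict(sample_id=f"{prefix}{t}_r{r}", tissue=t,
                                 muscle_class="skeletal", species=species, sex=sex, replicate=r))
        samples = pd.DataFrame(rows).set_index("sample_id")
        tissue_col = [tissues.index(t) for t in samples["tissue"]]
        mean_mat = mu[:, tissue_col] * len_kb[:, None] * (cfg.depth_mean / 1e6)
        counts = _nb_draw(sub_rng, mean_mat, cfg.nb_dispersion)
        counts_df = pd.DataFrame(counts, index=list(ann.index), columns=samples.index,
                                 dtype=np.int64)
        return counts_df, samples, ann, signA

    countsA, samplesA, annA, _ = build("mouse", "m", flip=False)
    countsB, samplesB, annB, _ = build("rat", "r", flip=True)

    dsA = ExpressionDataset(counts=countsA, samples=samplesA, transcripts=annA)
    dsB = ExpressionDataset(counts=countsB, samples=samplesB, transcripts=annB)
    table = OrthologTable.from_pairs(
        (a, b) for a, b in zip(annA.index, annB.index)
    )

    truth = SimTruth()
    idsA = list(annA.index)
    truth.de_transcripts = {idsA[i] for i in shared_idx}
    truth.concordance_same_direction = {idsA[i] for i in same_set}
    truth.concordant_direction_fraction = n_same / n_shared_de if n_shared_de else None
    return dsA, dsB, table, truth
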