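"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the three data layers of the pipeline:

* :func:`simulate_time_course` — per-gene mature-miRNA kinetics under
  dM/dt = b·P(t) − a·M(t), with piecewise-constant transcription pulses P(t).
  ``kinetics="exact"`` integrates the closed form piece by piece;
  ``kinetics="euler"`` instead emits the window-step discretization of the same
  linear model (the generative counterpart of the change-rate regression, which
  that regression recovers exactly on noiseless data).
* :func:`simulate_counts` — sequencing counts per window and replicate, drawn
  negative-binomially around means proportional to the true mature level, with
  a spike-in row for normalization.
* :func:`simulate_snp_panel` — 3'UTRs carrying planted polymorphic seed-target
  sites in a panel of homozygous inbred lines, with derived-allele counts drawn
  from a (1/i)·w^i site-frequency law (w = 1 neutral, w < 1 selection against
  the target allele) and an outgroup for polarization.

All randomness flows from ``SimConfig.rng_seed``; each generator uses an
independent deterministic stream derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .popgen import SeedTarget, enumerate_nontarget_variants, seed_target_hexamer
from .windows import DEFAULT_WINDOW_BOUNDS, TimeWindow, make_windows

__all__ = [
    "PopgenConfig",
    "SimConfig",
    "TrueKinetics",
    "SnpPanel",
    "SyntheticDataset",
    "random_kinetics_config",
    "simulate_time_course",
    "simulate_counts",
    "simulate_snp_panel",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Stream ids for per-stage child RNGs.
_STREAM_PARAMS, _STREAM_COUNTS, _STREAM_POPGEN = 0, 1, 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PopgenConfig:
    """Conditions for the SNP-panel generator.

    ``selection_weight`` may be a single weight for both gene classes or a
    mapping {"maternal": w, "zygotic": w}; a derived-target allele count i is
    drawn with probability proportional to (1/i)·w^i (and symmetrically
    (1/i)·w^(n-i) when the derived allele is the non-target variant), so w = 1
    is the neutral 1/i spectrum and w < 1 pushes target alleles toward low
    frequency.
    """

    n_lines: int = 205
    n_sites: int = 2000                 # planted sites per gene class per miRNA
    selection_weight: float | Mapping[str, float] = 1.0
    outgroup_divergence: float = 0.05   # probability the outgroup carries the derived allele
    mirna_seqs: Mapping[str, str] | None = None
    n_mirnas: int = 1                   # used only when mirna_seqs is None
    mature_length: int = 22
    utr_length: int = 200
    p_derived_target: float = 0.5       # probability the derived allele is the target
    missing_rate: float = 0.0
    cds_decoy_fraction: float = 0.0     # fraction of sites also covered by a CDS interval

    def weight_for(self, gene_class: str) -> float:
        if isinstance(self.selection_weight, Mapping):
            return float(self.selection_weight[gene_class])
        return float(self.selection_weight)

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("popgen.n_lines must be >= 2")
        if self.n_sites < 0:
            raise ValueError("popgen.n_sites must be >= 0")
        for cls in ("maternal", "zygotic"):
            w = self.weight_for(cls)
            if not 0 < w <= 1:
                raise ValueError(f"selection weight for {cls} must be in (0, 1], got {w}")
        if not 0 <= self.outgroup_divergence <= 1:
            raise ValueError("outgroup_divergence must be a probability")
        if self.utr_length < 6:
            raise ValueError("utr_length must be >= 6")


@dataclass
class SimConfig:
    """Full parameterization of one synthetic dataset.

    Per-gene kinetic parameters: degradation rate ``a`` (per hour, >= 0),
    production coefficient ``b`` (mature RPTS per pri-density unit per hour,
    > 0), initial mature level ``m0`` (RPTS) and transcription pulses
    (start_h, end_h, level) per gene.
    """

    a: np.ndarray                        # (n_genes,)
    b: np.ndarray
    m0: np.ndarray
    pulses: list[list[tuple[float, float, float]]]
    genes: list[str] | None = None
    window_bounds: Sequence[tuple[float, float]] = DEFAULT_WINDOW_BOUNDS
    kinetics: str = "exact"              # "exact" | "euler"
    n_replicates: int = 3
    library_depth: int = 1_000_000
    spikein_true_count: int = 10_000
    nb_dispersion: float = 0.05
    # The spike-in is a fixed synthetic oligo added per RNA mass; unlike gene
    # counts it carries no biological dispersion, so it defaults to Poisson.
    spikein_dispersion: float = 0.0
    popgen: PopgenConfig | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        n = self.a.size
        if not (self.b.size == n and self.m0.size == n and len(self.pulses) == n):
            raise ValueError("per-gene parameter arrays must share one length")
        if (self.a < 0).any():
            raise ValueError("degradation rates a must be >= 0")
        if (self.b < 0).any():
            raise ValueError("production coefficients b must be >= 0")
        if (self.m0 < 0).any():
            raise ValueError("initial levels M0 must be >= 0")
        if self.genes is None:
            self.genes = [f"mir_sim{i + 1:03d}" for i in range(n)]
        if len(self.genes) != n:
            raise ValueError("gene id list length mismatch")
        if self.kinetics not in ("exact", "euler"):
            raise ValueError(f"unknown kinetics mode {self.kinetics!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be > 0")
        if self.spikein_true_count <= 0:
            raise ValueError("spikein_true_count must be > 0")
        if self.nb_dispersion < 0 or self.spikein_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        make_windows(self.window_bounds)  # validates ordering
        if self.popgen is not None:
            self.popgen.validate()

    @property
    def n_genes(self) -> int:
        return int(self.a.size)

    def windows(self) -> list[TimeWindow]:
        return make_windows(self.window_bounds)


def random_kinetics_config(
    n_genes: int = 50,
    seed: int = 0,
    a_range: tuple[float, float] = (0.02, 0.5),
    b_range: tuple[float, float] = (0.5, 2.0),
    level_range: tuple[float, float] = (5.0, 500.0),
    pulse_style: str = "bursty",
    **overrides,
) -> SimConfig:
    """Draw a random but reproducible kinetic parameterization.

    ``pulse_style="bursty"`` gives each gene one or two transcription pulses at
    random windows (transient pri-miRNA peaks); ``"sustained"`` gives per-window
    production with mild (+-20%) level variation around a gene-specific base and
    starts each gene at its kinetic steady state, which keeps the discretized
    trajectories strictly positive.
    """
    rng = _rng(seed, _STREAM_PARAMS)
    bounds = overrides.get("window_bounds", DEFAULT_WINDOW_BOUNDS)
    wins = make_windows(bounds)
    a = rng.uniform(*a_range, size=n_genes)
    b = rng.uniform(*b_range, size=n_genes)
    base_level = np.exp(rng.uniform(np.log(level_range[0]), np.log(level_range[1]), size=n_genes))
    pulses: list[list[tuple[float, float, float]]] = []
    if pulse_style == "bursty":
        m0 = base_level * rng.uniform(0.0, 0.5, size=n_genes)
        for g in range(n_genes):
            n_pulse = int(rng.integers(1, 3))
            gene_pulses = []
            for _ in range(n_pulse):
                w0 = int(rng.integers(0, len(wins)))
                w1 = min(len(wins) - 1, w0 + int(rng.integers(1, 3)))
                level = base_level[g] * a[g] / b[g] * rng.uniform(0.5, 2.0)
                gene_pulses.append((wins[w0].start, wins[w1].end, level))
            pulses.append(gene_pulses)
    elif pulse_style == "sustained":
        p_base = base_level * a / b       # steady-state production for level base_level
        m0 = np.empty(n_genes)
        for g in range(n_genes):
            gene_pulses = [
                (w.start, w.end, p_base[g] * rng.uniform(0.8, 1.2)) for w in wins
            ]
            pulses.append(gene_pulses)
            m0[g] = b[g] * gene_pulses[0][2] / a[g] if a[g] > 0 else base_level[g]
    else:
        raise ValueError(f"unknown pulse_style {pulse_style!r}")
    overrides.setdefault("rng_seed", seed)
    return SimConfig(a=a, b=b, m0=m0, pulses=pulses, **overrides)


# ---------------------------------------------------------------------------
# Kinetic time courses


@dataclass
class TrueKinetics:
    """Ground-truth kinetic trajectories on the window grid.

    ``M`` holds mature levels (RPTS) at window midpoints; ``P`` the
    window-average transcription (pri-density units).
    """

    genes: list[str]
    windows: list[TimeWindow]
    a: np.ndarray
    b: np.ndarray
    m0: np.ndarray
    pulses: list[list[tuple[float, float, float]]]
    M: np.ndarray                        # (n_genes, n_windows)
    P: np.ndarray
    kinetics: str

    def mature_frame(self) -> pd.DataFrame:
        cols = [w.label for w in self.windows]
        return pd.DataFrame(self.M, index=pd.Index(self.genes, name="gene"), columns=cols)

    def pri_frame(self) -> pd.DataFrame:
        cols = [w.label for w in self.windows]
        return pd.DataFrame(self.P, index=pd.Index(self.genes, name="gene"), columns=cols)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "a_per_h": self.a,
                "b": self.b,
                "M0": self.m0,
                "pulses": [mio.format_pulse_spec(p) for p in self.pulses],
            }
        )


def _pulse_level(pulses: Sequence[tuple[float, float, float]], t: float) -> float:
    return sum(level for s, e, level in pulses if s <= t < e)


def _window_average_production(
    pulses: Sequence[tuple[float, float, float]], window: TimeWindow
) -> float:
    total = 0.0
    for s, e, level in pulses:
        overlap = min(e, window.end) - max(s, window.start)
        if overlap > 0:
            total += level * overlap
    return total / window.width


def _integrate_exact(
    a: float, b: float, m0: float, pulses, midpoints: Sequence[float]
) -> np.ndarray:
    """Piecewise closed form of dM/dt = b·P(t) − a·M with piecewise-constant P."""
    edges = {0.0}
    edges.update(t for s, e, _ in pulses for t in (s, e) if 0.0 < t <= midpoints[-1])
    edges.update(midpoints)
    grid = sorted(edges)
    m = m0
    out = []
    record = set(midpoints)
    if grid[0] in record:
        out.append(m)
    for t0, t1 in zip(grid, grid[1:]):
        p = _pulse_level(pulses, t0)
        dt = t1 - t0
        if a > 0:
            decay = np.exp(-a * dt)
            m = m * decay + (b * p / a) * (1.0 - decay)
        else:
            m = m + b * p * dt
        if t1 in record:
            out.append(m)
    return np.asarray(out)


def simulate_time_course(config: SimConfig, clip_negative: bool = False) -> TrueKinetics:
    """Integrate per-gene kinetics and report mature levels at window midpoints.

    ``kinetics="exact"`` uses the piecewise closed form
    M(t+Δ) = M e^{−aΔ} + (bP/a)(1 − e^{−aΔ}) (linear limit when a = 0).
    ``kinetics="euler"`` applies the window-step recurrence
    M_{k+1} = M_k + Δ_k (b P_{k+1} − a M_k) over midpoint gaps Δ_k, which is the
    model the change-rate regression assumes; a step driving M below zero
    raises unless ``clip_negative`` is set.
    """
    wins = config.windows()
    mids = [w.midpoint for w in wins]
    n_g, n_w = config.n_genes, len(wins)
    P = np.array(
        [[_window_average_production(config.pulses[g], w) for w in wins] for g in range(n_g)]
    )
    M = np.empty((n_g, n_w))
    if config.kinetics == "exact":
        for g in range(n_g):
            M[g] = _integrate_exact(
                float(config.a[g]), float(config.b[g]), float(config.m0[g]),
                config.pulses[g], mids,
            )
    else:  # euler
        gaps = np.diff(mids)
        M[:, 0] = config.m0
        for k in range(n_w - 1):
            step = gaps[k] * (config.b * P[:, k + 1] - config.a * M[:, k])
            nxt = M[:, k] + step
            if (nxt < 0).any():
                if clip_negative:
                    nxt = np.maximum(nxt, 0.0)
                else:
                    bad = np.asarray(config.genes)[nxt < 0][0]
                    raise ValueError(
                        f"euler kinetics drove {bad} negative at window {wins[k + 1].label}; "
                        "adjust parameters or pass clip_negative=True"
                    )
            M[:, k + 1] = nxt
    return TrueKinetics(
        genes=list(config.genes),
        windows=wins,
        a=config.a.copy(),
        b=config.b.copy(),
        m0=config.m0.copy(),
        pulses=[list(p) for p in config.pulses],
        M=M,
        P=P,
        kinetics=config.kinetics,
    )


# ---------------------------------------------------------------------------
# Sequencing counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    truth: TrueKinetics,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Draw per-replicate gene x window count tables with a SPIKEIN row.

    Expected gene counts are M_g x spikein_true_count / 1000 (so that RPTS
    computed against the spike-in row is unbiased for M_g); ``library_depth``
    rescales all means jointly relative to the nominal 10^6-read library.
    """
    rng = rng if rng is not None else _rng(config.rng_seed, _STREAM_COUNTS)
    depth_scale = config.library_depth / 1_000_000
    gene_mean = truth.M * config.spikein_true_count / 1000.0 * depth_scale
    spike_mean = config.spikein_true_count * depth_scale
    cols = [w.label for w in truth.windows]
    out = {}
    for r in range(config.n_replicates):
        counts = _nb_draw(rng, gene_mean, config.nb_dispersion)
        spike = _nb_draw(rng, np.full(len(cols), spike_mean), config.spikein_dispersion)
        df = pd.DataFrame(counts, index=pd.Index(truth.genes, name="gene"), columns=cols)
        df.loc[mio.SPIKEIN_ID] = spike
        out[f"rep{r + 1}"] = df
    return out


# ---------------------------------------------------------------------------
# SNP panel


@dataclass
class SnpPanel:
    """Synthetic UTRs, line panel and outgroup with per-site planted truth."""

    utr_seqs: dict[str, str]
    utr_bed: pd.DataFrame
    cds_bed: pd.DataFrame
    snps: mio.SnpTable
    gene_classes: pd.DataFrame
    ortholog_map: dict[str, str]
    mirna_seqs: dict[str, str]
    truth: pd.DataFrame


def _sfs_pmf(n_lines: int, w: float, derived_is_target: bool) -> np.ndarray:
    i = np.arange(1, n_lines, dtype=float)
    if derived_is_target:
        weights = (1.0 / i) * np.power(w, i)
    else:
        # Selection acts against the (ancestral) target allele: favour high
        # derived non-target counts symmetrically.
        weights = (1.0 / i) * np.power(w, n_lines - i)
    return weights / weights.sum()


def _random_mature(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


def simulate_snp_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SnpPanel:
    """Plant polymorphic seed-target sites in synthetic 3'UTRs.

    Each planted site gets its own gene (one UTR on its own contig).  The
    ancestral hexamer is written into the UTR (reference) sequence; the derived
    allele segregates at a count drawn from the (1/i)·w^i law of
    :class:`PopgenConfig`.  The outgroup carries the ancestral allele, flipped
    to the derived allele with probability ``outgroup_divergence``.
    """
    if config.popgen is None:
        raise ValueError("SimConfig.popgen is not set")
    pg = config.popgen
    rng = rng if rng is not None else _rng(config.rng_seed, _STREAM_POPGEN)

    if pg.mirna_seqs is not None:
        mirna_seqs = {k: str(v) for k, v in pg.mirna_seqs.items()}
    else:
        mirna_seqs = {
            f"mir_syn{i + 1}": _random_mature(rng, pg.mature_length)
            for i in range(pg.n_mirnas)
        }
    targets = {
        name: enumerate_nontarget_variants(seed_target_hexamer(seq, name))
        for name, seq in mirna_seqs.items()
    }

    utr_start = 100
    L = pg.n_lines
    lines = [f"line{i + 1:03d}" for i in range(L)]

    utr_seqs: dict[str, str] = {}
    utr_rows, cds_rows, class_rows, truth_rows = [], [], [], []
    snp_rows: list[dict] = []
    call_blocks: list[np.ndarray] = []
    ortholog_map: dict[str, str] = {}

    for cls in ("maternal", "zygotic"):
        w = pg.weight_for(cls)
        for mirna, st in targets.items():
            n = pg.n_sites
            if n == 0:
                continue
            target = st.target_hexamer
            # Per-site draws (vectorized where it matters).
            offsets = rng.integers(0, pg.utr_length - 6 + 1, size=n)
            var_pos = rng.integers(0, 6, size=n)
            var_base = np.empty(n, dtype="U1")
            for k in range(n):
                choices = [bch for bch in "ACGT" if bch != target[var_pos[k]]]
                var_base[k] = choices[rng.integers(0, 3)]
            derived_is_target = rng.random(n) < pg.p_derived_target
            pmf_t = _sfs_pmf(L, w, True)
            pmf_n = _sfs_pmf(L, w, False)
            counts = np.where(
                derived_is_target,
                rng.choice(np.arange(1, L), size=n, p=pmf_t),
                rng.choice(np.arange(1, L), size=n, p=pmf_n),
            )
            # Background sequence and planted ancestral hexamer.
            bg = _BASES[rng.integers(0, 4, size=(n, pg.utr_length))]
            # Per-line calls: `counts[k]` derived alleles at random lines.
            perm = rng.permuted(np.broadcast_to(np.arange(L), (n, L)), axis=1)
            calls = (perm < counts[:, None]).astype(np.int8)
            if pg.missing_rate > 0:
                calls[rng.random((n, L)) < pg.missing_rate] = -1
            in_cds = rng.random(n) < pg.cds_decoy_fraction
            flip_out = rng.random(n) < pg.outgroup_divergence

            for k in range(n):
                gene = f"{cls[:3]}_{mirna}_{k + 1:05d}"
                j = int(var_pos[k])
                variant_hex = target[:j] + str(var_base[k]) + target[j + 1 :]
                if derived_is_target[k]:
                    ancestral_hex, derived_base = variant_hex, target[j]
                else:
                    ancestral_hex, derived_base = target, str(var_base[k])
                row = bg[k]
                row[offsets[k] : offsets[k] + 6] = np.frombuffer(
                    ancestral_hex.encode(), dtype="S1"
                )
                utr_seqs[gene] = row.tobytes().decode()
                utr_rows.append((gene, utr_start, utr_start + pg.utr_length, gene, 0, "+"))
                pos = utr_start + int(offsets[k]) + j + 1  # 1-based
                ref_allele = ancestral_hex[j]
                site_id = f"{gene}:{pos}"
                snp_rows.append(
                    {"chrom": gene, "pos": pos, "ref": ref_allele, "alt": derived_base}
                )
                ortholog_map[site_id] = derived_base if flip_out[k] else ref_allele
                if in_cds[k]:
                    cds_rows.append((gene, pos - 3, pos + 2, f"{gene}_cds", 0, "+"))
                class_rows.append((gene, cls, 1.0))
                c = calls[k]
                n_derived = int((c == 1).sum())
                n_anc = int((c == 0).sum())
                if derived_is_target[k]:
                    n_target, n_non = n_derived, n_anc
                else:
                    n_target, n_non = n_anc, n_derived
                denom = n_target + n_non
                truth_rows.append(
                    {
                        "site_id": site_id,
                        "gene": gene,
                        "gene_class": cls,
                        "mirna": mirna,
                        "selection_weight": w,
                        "derived_is_target": bool(derived_is_target[k]),
                        "derived_count_planted": int(counts[k]),
                        "target_allele": "alt" if derived_is_target[k] else "ref",
                        "target_allele_freq": n_target / denom if denom else np.nan,
                        "in_cds": bool(in_cds[k]),
                        "outgroup_flipped": bool(flip_out[k]),
                    }
                )
            call_blocks.append(calls)

    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]
    snp_df = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])
    all_calls = (
        np.concatenate(call_blocks, axis=0) if call_blocks else np.zeros((0, L), dtype=np.int8)
    )
    return SnpPanel(
        utr_seqs=utr_seqs,
        utr_bed=pd.DataFrame(utr_rows, columns=bed_cols),
        cds_bed=pd.DataFrame(cds_rows, columns=bed_cols),
        snps=mio.SnpTable(df=snp_df, calls=all_calls, lines=lines),
        gene_classes=pd.DataFrame(class_rows, columns=["gene", "gene_class", "max_fpkm"]),
        ortholog_map=ortholog_map,
        mirna_seqs=mirna_seqs,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Full datasets


@dataclass
class SyntheticDataset:
    config: SimConfig
    truth: TrueKinetics
    counts: dict[str, pd.DataFrame]
    gene_meta: pd.DataFrame              # gene, five_prime_nt, multimapper_fraction
    snp_panel: SnpPanel | None


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run all generators for one config (kinetics, counts, optional SNP panel)."""
    truth = simulate_time_course(config)
    counts = simulate_counts(truth, config)
    meta_rng = _rng(config.rng_seed, _STREAM_PARAMS + 10)
    # Mature miRNAs are strongly 5'-U biased in vivo; emulate that bias.
    nts = meta_rng.choice(list("UACG"), size=config.n_genes, p=[0.55, 0.15, 0.15, 0.15])
    # Group ~40% of genes into polycistronic clusters of 2-4 members so the
    # clustered-miRNA comparisons have realistic input.
    cluster_id = np.full(config.n_genes, ".", dtype=object)
    order = meta_rng.permutation(config.n_genes)
    pos, cl = 0, 0
    while pos < int(0.4 * config.n_genes):
        size = int(meta_rng.integers(2, 5))
        members = order[pos : pos + size]
        if len(members) < 2:
            break
        cl += 1
        cluster_id[members] = f"cl{cl}"
        pos += size
    gene_meta = pd.DataFrame(
        {
            "gene": config.genes,
            "five_prime_nt": nts,
            "multimapper_fraction": meta_rng.uniform(0.0, 0.15, size=config.n_genes),
            "cluster_id": cluster_id,
        }
    )
    panel = simulate_snp_panel(config) if config.popgen is not None else None
    return SyntheticDataset(
        config=config, truth=truth, counts=counts, gene_meta=gene_meta, snp_panel=panel
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of a synthetic dataset; returns the path map.

    Re-reading the files through the :mod:`mirdyn.io` readers reproduces the
    in-memory values exactly (round-trip contract).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def reg(key: str, name: str) -> Path:
        paths[key] = out / name
        return paths[key]

    mio.write_kinetic_truth(dataset.truth.truth_frame(), reg("truth_kinetics", "truth_kinetics.tsv"))
    mio.write_time_course(dataset.truth.mature_frame(), reg("true_mature", "true_mature_rpts.tsv"))
    mio.write_time_course(dataset.truth.pri_frame(), reg("pri_density", "pri_density.tsv"))
    for rep, df in dataset.counts.items():
        mio.write_time_course(df, reg(f"counts_{rep}", f"counts_{rep}.tsv"))
    dataset.gene_meta.to_csv(reg("gene_meta", "gene_meta.tsv"), sep="\t", index=False)
    if dataset.snp_panel is not None:
        panel = dataset.snp_panel
        mio.write_fasta(panel.utr_seqs, reg("utr_fasta", "utrs.fa"))
        mio.write_bed(panel.utr_bed, reg("utr_bed", "utrs.bed"))
        mio.write_bed(panel.cds_bed, reg("cds_bed", "cds.bed"))
        mio.write_snp_tsv(panel.snps, reg("snps", "snps.tsv"))
        mio.write_gene_classes(panel.gene_classes, reg("gene_classes", "gene_classes.tsv"))
        mio.write_ortholog_map(panel.ortholog_map, reg("ortholog_map", "ortholog_map.tsv"))
        mio.write_fasta(panel.mirna_seqs, reg("mature_mirnas", "mature_mirnas.fa"))
        panel.truth.to_csv(reg("popgen_truth", "popgen_truth.tsv"), sep="\t", index=False)
    return paths
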