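"""Synthetic data with the statistical structure of a bleomycin-injury
time course, plus planted ground truth for parameter-recovery tests.

The generator emulates a longitudinal whole-lung droplet scRNA-seq design:
an uninjured control day 0 plus post-injury sampling days, a few replicate
mice per time point, cell types with planted marker genes, a shared
ambient-RNA background mixed into every droplet, time-varying cell-type
frequencies, per-cell-type temporally regulated genes whose *detection
probability* follows a planted logit-scale curve, gamma-Poisson (negative
binomial) count noise and lognormal library-size variation.  Matched bulk
RNA / in silico bulk / proteomics-like triplets share a planted condition
effect.

Everything is driven by a single integer seed through
``numpy.random.default_rng`` and is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import BulkProfile, CellTable, ValidationError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_timecourse",
    "simulate_detection_summaries",
    "simulate_spliced_unspliced",
    "simulate_bulk_multiomics",
    "simulate_rl_catalog",
    "bump_curve",
]

#: default sampling design: PBS control (day 0) + six post-injury days
DEFAULT_DAYS = (0.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0)


def bump_curve(times, peak: float = 10.0, width: float = 7.0) -> np.ndarray:
    """Smooth injury-response curve in [0, 1]: zero at baseline, Gaussian
    bump peaking at ``peak`` days with scale ``width``."""
    t = np.asarray(times, dtype=float)
    return np.exp(-0.5 * ((t - peak) / width) ** 2)


@dataclass
class SimConfig:
    """Parameters of the synthetic time course.

    Defaults follow the study design being emulated: 7 time points
    (control day 0 plus days 3-28), 4 replicate mice per time point
    (28 samples), ~1000 cells per mouse.
    """

    n_timepoints: int = 7
    replicates_per_timepoint: int = 4
    n_celltypes: int = 12
    n_genes: int = 2000
    markers_per_celltype: int = 15
    ambient_gene_count: int = 40
    ambient_fraction: float = 0.1
    temporal_gene_count: int = 10  # per cell type
    temporal_effect: float = 2.0  # logit-scale detection shift amplitude
    temporal_baseline_detection: float = 0.3
    mean_umi_per_cell: float = 1500.0
    dispersion: float = 0.3
    cells_per_sample: int = 1000
    marker_fold: float = 10.0
    type_divergence: float = 0.7  # lognormal sd of type-specific deviation from the shared baseline
    frequency_trajectories: np.ndarray | None = None  # (n_celltypes, n_timepoints)
    days: tuple = DEFAULT_DAYS
    seed: int = 0

    def __post_init__(self):
        if len(self.days) != self.n_timepoints:
            self.days = tuple(np.linspace(0, 28, self.n_timepoints))
        for name in ("ambient_fraction",):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.dispersion < 0 or self.mean_umi_per_cell <= 0:
            raise ValidationError("dispersion must be >=0 and mean UMI positive")
        if self.frequency_trajectories is not None:
            f = np.asarray(self.frequency_trajectories, dtype=float)
            if f.shape != (self.n_celltypes, self.n_timepoints):
                raise ValidationError("frequency_trajectories must be (n_celltypes, n_timepoints)")
            if (f < 0).any() or not np.allclose(f.sum(axis=0), 1.0, atol=1e-8):
                raise ValidationError("frequencies at each time must be nonnegative and sum to 1")
            self.frequency_trajectories = f

    @property
    def celltypes(self):
        return [f"type{i:02d}" for i in range(self.n_celltypes)]

    @property
    def genes(self):
        return np.array([f"gene{i:04d}" for i in range(self.n_genes)], dtype=object)


@dataclass
class GroundTruth:
    """Planted simulation truth used by recovery tests."""

    marker_assignment: dict = field(default_factory=dict)  # gene -> cell type
    ambient_genes: set = field(default_factory=set)
    temporal_genes: dict = field(default_factory=dict)  # cell type -> {gene: [p(t) per day]}
    true_frequencies: pd.DataFrame | None = None  # sample x cell type
    doublet_parent_pairs: list = field(default_factory=list)
    condition_effect_genes: list = field(default_factory=list)
    days: tuple = ()
    type_profiles: pd.DataFrame | None = None  # cell type x gene expression fractions

    def markers_of(self, cell_type: str) -> list:
        return sorted(g for g, c in self.marker_assignment.items() if c == cell_type)

    def to_json(self, path):
        payload = {
            "marker_assignment": self.marker_assignment,
            "ambient_genes": sorted(self.ambient_genes),
            "temporal_genes": {
                ct: {g: list(map(float, curve)) for g, curve in d.items()}
                for ct, d in self.temporal_genes.items()
            },
            "true_frequencies": (
                None
                if self.true_frequencies is None
                else self.true_frequencies.to_dict(orient="index")
            ),
            "doublet_parent_pairs": self.doublet_parent_pairs,
            "condition_effect_genes": list(self.condition_effect_genes),
            "days": list(self.days),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _frequency_trajectories(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-type relative frequencies over time (columns sum to 1).

    A random subset of types is 'injury responsive' with a logit-scale bump
    peaking somewhere in the time course (emulating e.g. M2 macrophages or
    myofibroblasts transiently expanding after injury)."""
    if cfg.frequency_trajectories is not None:
        return cfg.frequency_trajectories
    t = np.asarray(cfg.days, dtype=float)
    base = rng.normal(0.0, 0.4, size=cfg.n_celltypes)
    logits = np.tile(base[:, None], (1, cfg.n_timepoints))
    n_dyn = min(cfg.n_celltypes, max(2, cfg.n_celltypes // 3))
    dynamic = rng.choice(cfg.n_celltypes, size=n_dyn, replace=False)
    for c in dynamic:
        peak = rng.uniform(3, 28)
        width = rng.uniform(4, 10)
        amp = rng.uniform(0.8, 2.0) * rng.choice([-1.0, 1.0])
        logits[c] += amp * bump_curve(t, peak, width)
    f = np.exp(logits)
    return f / f.sum(axis=0, keepdims=True)


def _expression_profiles(cfg: SimConfig, rng: np.random.Generator):
    """Per-type multinomial expression profiles with elevated markers, plus
    the shared ambient background profile concentrated on ambient genes."""
    G, C = cfg.n_genes, cfg.n_celltypes
    genes = cfg.genes
    n_marker = C * cfg.markers_per_celltype
    if n_marker + cfg.ambient_gene_count > G:
        raise ValidationError("gene universe too small for markers + ambient genes")
    order = rng.permutation(G)
    marker_idx = order[:n_marker].reshape(C, cfg.markers_per_celltype)
    ambient_idx = order[n_marker : n_marker + cfg.ambient_gene_count]

    baseline = rng.gamma(shape=0.4, scale=1.0, size=G) + 1e-4
    profiles = np.empty((C, G))
    for c in range(C):
        w = baseline * np.exp(rng.normal(0.0, cfg.type_divergence, size=G))
        w[marker_idx[c]] *= cfg.marker_fold
        profiles[c] = w / w.sum()

    amb = baseline.copy()
    amb /= amb.sum()
    amb *= 0.3
    amb[ambient_idx] += 0.7 / cfg.ambient_gene_count
    amb /= amb.sum()

    marker_assignment = {
        str(genes[g]): cfg.celltypes[c]
        for c in range(C)
        for g in marker_idx[c]
    }
    return profiles, amb, marker_assignment, marker_idx, ambient_idx


def simulate_timecourse(config: SimConfig):
    """Simulate the full longitudinal CellTable and its ground truth.

    Per sample, cell-type labels are drawn from the true frequencies at
    that time; each cell's counts are a gamma-Poisson draw around the
    mixture ``(1-ambient_fraction) * type profile + ambient_fraction *
    ambient profile`` scaled by a lognormal library size.  Temporal genes
    are regenerated through an explicit detection gate so that their
    per-cell detection probability follows the planted logit curve.

    Returns
    -------
    (CellTable, GroundTruth)
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    freqs = _frequency_trajectories(cfg, rng)
    profiles, ambient, marker_assignment, marker_idx, ambient_idx = _expression_profiles(cfg, rng)
    mix = (1.0 - cfg.ambient_fraction) * profiles + cfg.ambient_fraction * ambient

    # temporal genes: disjoint from markers and ambient, one owning type each
    used = set(np.concatenate([marker_idx.ravel(), ambient_idx]))
    free = np.array([g for g in range(cfg.n_genes) if g not in used])
    need = cfg.temporal_gene_count * cfg.n_celltypes
    if need > len(free):
        raise ValidationError("not enough free genes for temporal genes")
    temporal_idx = rng.choice(free, size=need, replace=False).reshape(
        cfg.n_celltypes, cfg.temporal_gene_count
    )
    days = np.asarray(cfg.days, dtype=float)
    genes = cfg.genes
    base_logit = np.log(cfg.temporal_baseline_detection / (1 - cfg.temporal_baseline_detection))
    temporal_truth: dict = {ct: {} for ct in cfg.celltypes}
    temporal_curves = np.empty((cfg.n_celltypes, cfg.temporal_gene_count, len(days)))
    for c in range(cfg.n_celltypes):
        for j in range(cfg.temporal_gene_count):
            peak = rng.uniform(3, 24)
            width = rng.uniform(4, 9)
            sign = rng.choice([-1.0, 1.0])
            logit = base_logit + sign * cfg.temporal_effect * bump_curve(days, peak, width)
            p = 1.0 / (1.0 + np.exp(-logit))
            temporal_curves[c, j] = p
            temporal_truth[cfg.celltypes[c]][str(genes[temporal_idx[c, j]])] = p

    sigma = 0.35  # lognormal library-size spread
    blocks, cell_ids, obs_rows = [], [], []
    freq_rows = {}
    k = 0
    for ti, day in enumerate(days):
        for rep in range(cfg.replicates_per_timepoint):
            sname = f"d{day:g}_r{rep}"
            labels = rng.choice(cfg.n_celltypes, size=cfg.cells_per_sample, p=freqs[:, ti])
            lib = rng.lognormal(
                mean=np.log(cfg.mean_umi_per_cell) - sigma**2 / 2, sigma=sigma,
                size=cfg.cells_per_sample,
            )
            lam = mix[labels] * lib[:, None]
            if cfg.dispersion > 0:
                lam = lam * rng.gamma(1.0 / cfg.dispersion, cfg.dispersion, size=lam.shape)
            counts = rng.poisson(lam)
            # detection-gated temporal genes, per owning type
            for c in range(cfg.n_celltypes):
                rows = np.flatnonzero(labels == c)
                if len(rows) == 0 or cfg.temporal_gene_count == 0:
                    continue
                p = temporal_curves[c, :, ti]
                det = rng.random((len(rows), cfg.temporal_gene_count)) < p
                mag = 1 + rng.poisson(0.6, size=det.shape)
                counts[np.ix_(rows, temporal_idx[c])] = det * mag
            blocks.append(sp.csr_matrix(counts))
            cell_ids.extend(f"{sname}_c{j:04d}" for j in range(cfg.cells_per_sample))
            for j in range(cfg.cells_per_sample):
                obs_rows.append(
                    (sname, day, cfg.celltypes[labels[j]], bool(day == 0))
                )
            freq_rows[sname] = freqs[:, ti]
            k += 1

    obs = pd.DataFrame(obs_rows, columns=["sample", "time_days", "label", "is_control"])
    table = CellTable(
        counts=sp.vstack(blocks).tocsr(),
        gene_ids=genes,
        cell_ids=np.asarray(cell_ids, dtype=object),
        obs=obs,
    )
    truth = GroundTruth(
        marker_assignment=marker_assignment,
        ambient_genes={str(genes[g]) for g in ambient_idx},
        temporal_genes=temporal_truth,
        true_frequencies=pd.DataFrame.from_dict(
            freq_rows, orient="index", columns=cfg.celltypes
        ),
        days=tuple(days),
        type_profiles=pd.DataFrame(mix, index=cfg.celltypes, columns=genes),
    )
    return table, truth


def simulate_detection_summaries(
    n_genes: int,
    days=DEFAULT_DAYS,
    replicates: int = 4,
    cells_per_sample: int = 30,
    effect: float = 0.0,
    n_shifted: int = 0,
    baseline_detection=(0.05, 0.5),
    seed: int = 0,
):
    """Sample-level binomial detection summaries for calibration and power
    studies of the temporal detection-rate model.

    For each gene, a baseline detection probability is drawn uniformly from
    ``baseline_detection``; the first ``n_shifted`` genes additionally get a
    logit-scale shift of amplitude ``effect`` following a smooth injury
    bump.  Detected-cell counts are ``k ~ Binomial(cells_per_sample, p(t))``
    for each of ``len(days) * replicates`` samples.

    Returns
    -------
    dict with keys ``k`` (genes x samples), ``n``, ``times``, ``offsets``
    (zeros), ``shifted`` (boolean per gene).
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    times = np.repeat(days, replicates)
    S = len(times)
    lo, hi = baseline_detection
    p0 = rng.uniform(lo, hi, size=n_genes)
    logit0 = np.log(p0 / (1 - p0))
    logit = np.tile(logit0[:, None], (1, S))
    shifted = np.zeros(n_genes, dtype=bool)
    shifted[:n_shifted] = True
    if n_shifted and effect != 0.0:
        for g in range(n_shifted):
            peak = rng.uniform(3, 24)
            width = rng.uniform(4, 9)
            logit[g] += effect * bump_curve(times, peak, width)
    p = 1.0 / (1.0 + np.exp(-logit))
    n = np.full(S, cells_per_sample, dtype=int)
    k = rng.binomial(n[None, :], p)
    return {
        "k": k,
        "n": n,
        "times": times,
        "offsets": np.zeros(S),
        "shifted": shifted,
    }


def simulate_spliced_unspliced(
    config: SimConfig,
    induction_times,
    n_genes: int = 30,
    n_induced: int = 3,
    steady_ratio: float = 0.25,
    induced_fold: float = 4.0,
):
    """Simulate spliced/unspliced count layers with transcriptional
    induction at the given time points.

    For induced genes the unspliced/spliced rate ratio is
    ``steady_ratio * induced_fold`` at induction times and ``steady_ratio``
    elsewhere; other genes sit at the steady-state ratio throughout.  One
    all-zero gene is always included as a degenerate case.

    Returns
    -------
    (CellTable with ``spliced``/``unspliced`` layers, truth dict)
    """
    cfg = config
    days = np.asarray(cfg.days, dtype=float)
    induction_times = np.asarray(induction_times, dtype=float)
    unknown = set(induction_times) - set(days)
    if unknown:
        raise ValidationError(f"unknown induction time points: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = np.array([f"sgene{i:03d}" for i in range(n_genes)], dtype=object)
    spliced_rate = rng.uniform(1.0, 5.0, size=n_genes)
    spliced_rate[-1] = 0.0  # degenerate zero-count gene
    induced = np.zeros(n_genes, dtype=bool)
    induced[:n_induced] = True
    induced[-1] = False

    s_blocks, u_blocks, cell_ids, obs_rows = [], [], [], []
    for day in days:
        is_induced_time = day in set(induction_times)
        for rep in range(cfg.replicates_per_timepoint):
            sname = f"d{day:g}_r{rep}"
            ratio = np.full(n_genes, steady_ratio)
            if is_induced_time:
                ratio[induced] *= induced_fold
            ncell = cfg.cells_per_sample
            s = rng.poisson(np.tile(spliced_rate, (ncell, 1)))
            u = rng.poisson(np.tile(spliced_rate * ratio, (ncell, 1)))
            s_blocks.append(sp.csr_matrix(s))
            u_blocks.append(sp.csr_matrix(u))
            cell_ids.extend(f"{sname}_c{j:04d}" for j in range(ncell))
            obs_rows.extend((sname, day) for _ in range(ncell))

    spliced = sp.vstack(s_blocks).tocsr()
    unspliced = sp.vstack(u_blocks).tocsr()
    obs = pd.DataFrame(obs_rows, columns=["sample", "time_days"])
    table = CellTable(
        counts=(spliced + unspliced).tocsr(),
        gene_ids=genes,
        cell_ids=np.asarray(cell_ids, dtype=object),
        obs=obs,
        layers={"spliced": spliced, "unspliced": unspliced},
    )
    truth = {
        "induced_genes": [str(g) for g in genes[induced]],
        "zero_gene": str(genes[-1]),
        "steady_ratio": steady_ratio,
        "induced_ratio": steady_ratio * induced_fold,
        "induction_times": sorted(float(t) for t in induction_times),
    }
    return table, truth


def simulate_bulk_multiomics(
    config: SimConfig,
    n_condition_genes: int = 100,
    effect_size: float = 1.5,
    noise_sd: float = 0.25,
    modality_sd: float = 1.0,
):
    """Three modality-matched bulk profiles sharing a planted condition effect.

    RNA-seq-like and in silico bulk matrices are Poisson counts around
    log2-scale means; the proteomics-like matrix carries log intensities
    directly.  ``n_condition_genes`` genes receive a shared log2 condition
    effect of magnitude ~``effect_size`` in the injured condition; each
    modality additionally has gene-wise offsets (scale ``modality_sd``)
    and sample noise (``noise_sd``).

    Returns
    -------
    (BulkProfile rna, BulkProfile insilico, BulkProfile protein, GroundTruth)
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)
    reps = cfg.replicates_per_timepoint
    if reps < 2:
        raise ValidationError("need >=2 samples per condition")
    genes = cfg.genes
    G = len(genes)
    if n_condition_genes > G:
        raise ValidationError("n_condition_genes exceeds gene universe")
    cond_idx = rng.choice(G, size=n_condition_genes, replace=False)
    mu = rng.normal(6.0, 1.5, size=G)  # baseline log2 abundance
    delta = np.zeros(G)
    delta[cond_idx] = rng.uniform(0.8, 1.2, size=n_condition_genes) * effect_size
    delta[cond_idx] *= rng.choice([-1.0, 1.0], size=n_condition_genes)

    conditions = ["control"] * reps + ["injured"] * reps
    is_inj = np.array([c == "injured" for c in conditions], dtype=float)

    def _rna(modality):
        off = rng.normal(0.0, modality_sd, size=G)
        logmean = mu[None, :] + off[None, :] + is_inj[:, None] * delta[None, :]
        logmean = logmean + rng.normal(0.0, noise_sd, size=(2 * reps, G))
        counts = rng.poisson(np.clip(2.0 ** logmean, 0, 1e7) / 8.0)
        idx = [f"{modality}_{c}_{i}" for i, c in enumerate(conditions)]
        values = pd.DataFrame(counts, index=idx, columns=genes)
        meta = pd.DataFrame({"condition": conditions, "modality": modality}, index=idx)
        return BulkProfile(values=values, sample_meta=meta)

    rna = _rna("bulk")
    insilico = _rna("insilico")

    off_p = rng.normal(0.0, modality_sd, size=G)
    logint = mu[None, :] + off_p[None, :] + is_inj[:, None] * delta[None, :]
    logint = logint + rng.normal(0.0, noise_sd, size=(2 * reps, G))
    idx = [f"protein_{c}_{i}" for i, c in enumerate(conditions)]
    protein = BulkProfile(
        values=pd.DataFrame(logint, index=idx, columns=genes),
        sample_meta=pd.DataFrame({"condition": conditions, "modality": "protein"}, index=idx),
    )
    truth = GroundTruth(condition_effect_genes=[str(genes[g]) for g in cond_idx])
    return rna, insilico, protein, truth


def simulate_composition_bulk(
    config: SimConfig,
    shifted_type: int = 0,
    fold: float = 3.0,
    n_per_condition: int = 4,
    total_counts: float = 2e6,
    freq_jitter: float = 0.05,
    seed: int | None = None,
):
    """Bulk RNA profiles whose injured condition carries a planted fold
    change in one cell type's contribution.

    Control samples mix the cell-type expression profiles at baseline
    frequencies; in injured samples the ``shifted_type``'s frequency is
    multiplied by ``fold`` (then renormalized).  Counts are Poisson around
    the mixed profile at ``total_counts`` library size.  ``freq_jitter``
    is the lognormal sd of per-sample composition variability (mouse to
    mouse); set it to 0 to hold composition exactly fixed within each
    condition, the appropriate null for calibration studies.  Returns (BulkProfile, GroundTruth) where the truth carries the
    planted marker assignment, true frequencies per condition and the
    shifted type's name in ``condition_effect_genes``-style metadata.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    profiles, _, marker_assignment, _, _ = _expression_profiles(cfg, rng)
    base = rng.dirichlet(np.full(cfg.n_celltypes, 8.0))
    inj = base.copy()
    inj[shifted_type] *= fold
    inj /= inj.sum()

    rows, idx, conds = [], [], []
    for cond, freq in (("control", base), ("injured", inj)):
        for r in range(n_per_condition):
            jitter = freq * rng.lognormal(0.0, freq_jitter, size=cfg.n_celltypes)
            jitter /= jitter.sum()
            lam = total_counts * (jitter @ profiles)
            rows.append(rng.poisson(lam))
            idx.append(f"{cond}_{r}")
            conds.append(cond)
    values = pd.DataFrame(rows, index=idx, columns=cfg.genes)
    meta = pd.DataFrame({"condition": conds, "modality": "bulk"}, index=idx)
    truth = GroundTruth(
        marker_assignment=marker_assignment,
        true_frequencies=pd.DataFrame(
            [base, inj], index=["control", "injured"], columns=cfg.celltypes
        ),
    )
    return BulkProfile(values=values, sample_meta=meta), truth, cfg.celltypes[shifted_type]


def simulate_rl_catalog(
    truth: GroundTruth,
    max_pairs_per_edge: int = 3,
    n_decoy_pairs: int = 20,
    decoy_genes=None,
    seed: int = 0,
):
    """Receptor-ligand catalog with a known planted number of pairs spanning
    each ordered cell-type pair.

    For every ordered pair (A, B) of cell types with markers, 0 to
    ``max_pairs_per_edge`` catalog rows are planted with the ligand drawn
    from A's markers and the receptor from B's markers.  Decoy pairs over
    non-marker genes (``decoy_genes``) are appended; they span no marker
    sets and contribute no edges.

    Returns
    -------
    (catalog DataFrame with columns ligand/receptor, dict (A, B) -> weight)
    """
    rng = np.random.default_rng(seed)
    celltypes = sorted(set(truth.marker_assignment.values()))
    markers = {ct: truth.markers_of(ct) for ct in celltypes}
    rows, weights = [], {}
    for a in celltypes:
        for b in celltypes:
            k = int(rng.integers(0, max_pairs_per_edge + 1))
            k = min(k, len(markers[a]), len(markers[b]))
            pairs = set()
            guard = 0
            while len(pairs) < k and guard < 100:
                lig = markers[a][rng.integers(len(markers[a]))]
                rec = markers[b][rng.integers(len(markers[b]))]
                if a == b and lig == rec:
                    guard += 1
                    continue
                pairs.add((lig, rec))
                guard += 1
            for lig, rec in sorted(pairs):
                rows.append((lig, rec))
            weights[(a, b)] = len(pairs)
    if decoy_genes is not None and n_decoy_pairs > 0:
        decoy = [g for g in decoy_genes if g not in truth.marker_assignment]
        for _ in range(n_decoy_pairs):
            if len(decoy) < 2:
                break
            i, j = rng.choice(len(decoy), size=2, replace=False)
            rows.append((decoy[i], decoy[j]))
    catalog = pd.DataFrame(rows, columns=["ligand", "receptor"]).drop_duplicates()
    return catalog.reset_index(drop=True), weights
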