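"""End-to-end orchestration: simulate -> preprocess -> PLI -> hubs -> stats.

Every stage's artifacts are persisted as delimited text (per-subject PLI
matrices, tidy betweenness tables, ANOVA / post hoc / correlation tables,
top-edge lists) so any stage can be re-run in isolation from saved
output, and two runs with the same config and seed produce byte-identical
files.  A JSON manifest records the config echo, seed, package version,
per-band epoch counts, and any disconnected-graph occurrences (PLI values
of exactly zero sever edges, which silently changes shortest-path
structure and is worth noticing).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from . import __version__
from .connectivity import ConnectivityMatrix, PhaseEpochs, subject_connectivity
from .group_stats import (
    AnovaResult,
    CorrelationResult,
    GatingError,
    PosthocResult,
    fdr_across_bands,
    paired_ttest,
    pearson_corr,
    posthoc_ttests,
    rm_anova_mixed,
    rm_anova_prepost,
    top_edges,
)
from .hubgraph import hub_profile
from .montage_io import (
    DEFAULT_MONTAGE,
    EEGRecording,
    Montage,
    SubjectMeta,
    read_metadata,
    read_recording,
    write_matrix,
    write_metadata,
    write_recording,
)
from .preprocess import (
    BANDS,
    DEFAULT_EPOCH_LEN_S,
    DEFAULT_FILTER_ORDER,
    BandEpochs,
    BandSpec,
    FilterSpec,
    design_bandpass,
    design_notch,
    filter_data,
    segment_epochs,
)
from .synthetic_data import (
    BprsModel,
    CohortConfig,
    HubSpec,
    default_hubs_by_group,
    generate_cohort,
)

#: (electrode, band) sites examined for clinical-score / age correlations;
#: the planted-contrast sites of the default scenario.
INTEREST_SITES = (("Fz", "beta"), ("Pz", "gamma"), ("O1", "gamma"))


@dataclass
class PreprocessSettings:
    filter_order: int = DEFAULT_FILTER_ORDER
    window: str = "hamming"
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S
    drop_edge_epochs: bool = True
    notch_enabled: bool = False
    bands: tuple[BandSpec, ...] = BANDS


@dataclass
class StatsSettings:
    alpha: float = 0.05
    q_threshold: float = 0.05
    top_edge_fraction: float = 0.2
    interest_sites: tuple[tuple[str, str], ...] = INTEREST_SITES


@dataclass
class RunConfig:
    seed: int = 0
    simulate: Optional[CohortConfig] = None
    input_dir: Optional[Path] = None
    metadata_path: Optional[Path] = None
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("config needs exactly one input source: simulate or input_dir")


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------

def _cohort_config_from_dict(d: Mapping, seed: int) -> CohortConfig:
    d = dict(d)
    kwargs: dict = {"seed": int(d.pop("seed", seed))}
    if "n_per_group" in d:
        kwargs["n_per_group"] = {str(k): int(v) for k, v in d.pop("n_per_group").items()}
    for key in ("duration_s", "fs", "common_source_gain", "noise_gain", "coupling_jitter_sd"):
        if key in d:
            kwargs[key] = float(d.pop(key))
    if "band_amplitude_uv" in d:
        kwargs["band_amplitude_uv"] = {
            str(k): float(v) for k, v in d.pop("band_amplitude_uv").items()}
    if "bprs" in d:
        b = d.pop("bprs")
        kwargs["bprs_model"] = BprsModel(mean=float(b.get("mean", 50.0)),
                                         sd=float(b.get("sd", 12.0)),
                                         rho=float(b.get("rho", 0.0)))
    if "hubs_by_group" in d:
        raw = d.pop("hubs_by_group")
        kwargs["hubs_by_group"] = {
            g: tuple(
                HubSpec(electrode=h["electrode"], band=h["band"],
                        targets=tuple(h["targets"]),
                        coupling=float(h.get("coupling", 0.8)),
                        lag=float(h.get("lag", np.pi / 4)))
                for h in hubs
            )
            for g, hubs in raw.items()
        }
    else:
        strong = float(d.pop("strong_coupling", 0.85))
        weak = float(d.pop("weak_coupling", 0.15))
        kwargs["hubs_by_group"] = default_hubs_by_group(strong=strong, weak=weak)
    if d:
        raise ValueError(f"unknown simulate config keys: {sorted(d)}")
    return CohortConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON run config."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    simulate = None
    input_dir = metadata_path = None
    if "simulate" in raw:
        simulate = _cohort_config_from_dict(raw["simulate"] or {}, seed)
    if "input" in raw:
        inp = raw["input"]
        input_dir = Path(inp["recordings_dir"])
        metadata_path = Path(inp["metadata"])
    pp = raw.get("preprocess", {})
    pre = PreprocessSettings(
        filter_order=int(pp.get("filter_order", DEFAULT_FILTER_ORDER)),
        window=str(pp.get("window", "hamming")),
        epoch_len_s=float(pp.get("epoch_len_s", DEFAULT_EPOCH_LEN_S)),
        drop_edge_epochs=bool(pp.get("drop_edge_epochs", True)),
        notch_enabled=bool(pp.get("notch_enabled", False)),
    )
    st = raw.get("stats", {})
    stats = StatsSettings(
        alpha=float(st.get("alpha", 0.05)),
        q_threshold=float(st.get("q_threshold", 0.05)),
        top_edge_fraction=float(st.get("top_edge_fraction", 0.2)),
        interest_sites=tuple(
            (str(e), str(b)) for e, b in st.get("interest_sites", INTEREST_SITES)
        ),
    )
    return RunConfig(seed=seed, simulate=simulate, input_dir=input_dir,
                     metadata_path=metadata_path, preprocess=pre, stats=stats)


# ---------------------------------------------------------------------------
# Connectivity + hubs for whole cohorts
# ---------------------------------------------------------------------------

def _multiband_filter(X: np.ndarray, taps: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Reflect-padded 'valid' FIR filtering of every band, sharing one
    forward FFT of the input across bands."""
    from scipy import fft as sfft

    ntaps = {len(t) for t in taps.values()}
    if len(ntaps) != 1:
        raise ValueError("all band filters must share one length")
    m = ntaps.pop()
    half = (m - 1) // 2
    Xp = np.pad(X, ((0, 0), (half, half)), mode="reflect")
    nfft = sfft.next_fast_len(Xp.shape[1] + m - 1, real=True)
    F = sfft.rfft(Xp, nfft, axis=-1)
    out = {}
    for name, t in taps.items():
        H = sfft.rfft(t.astype(X.dtype, copy=False), nfft)
        y = sfft.irfft(F * H, nfft, axis=-1)
        out[name] = np.ascontiguousarray(y[:, m - 1 : m - 1 + X.shape[1]])
    return out


def cohort_connectivity(
    recs: Sequence[EEGRecording],
    settings: PreprocessSettings = PreprocessSettings(),
    chunk_bytes: float = 2e8,
) -> dict[str, list[ConnectivityMatrix]]:
    """Band-filter, epoch and PLI-estimate every recording.

    Subjects are processed in chunks, with one batched FIR convolution per
    band and chunk; numerically identical to the per-subject path.
    Returns {band name: [ConnectivityMatrix per subject, input order]}.
    """
    if not recs:
        return {band.name: [] for band in settings.bands}
    fs = recs[0].fs
    n = recs[0].n_samples
    n_ch = len(recs[0].montage)
    for r in recs:
        if r.fs != fs or r.n_samples != n:
            raise ValueError("cohort recordings must share fs and length")

    per_subject = n_ch * n * 4
    chunk = max(1, int(chunk_bytes / max(per_subject, 1)))
    out: dict[str, list[ConnectivityMatrix]] = {b.name: [] for b in settings.bands}
    notch = (design_notch(fs, order=settings.filter_order, window=settings.window)
             if settings.notch_enabled else None)
    taps = {
        b.name: design_bandpass(FilterSpec(b, settings.filter_order, settings.window), fs)
        for b in settings.bands
    }
    epoch_samples = int(round(settings.epoch_len_s * fs))
    for start in range(0, len(recs), chunk):
        block = recs[start : start + chunk]
        S = len(block)
        # 2-D layout (subjects*channels x samples) with one shared forward
        # FFT across bands; same reflect-padded linear convolution as
        # filter_data, so per-subject and batched routes agree.
        X = np.stack([r.data for r in block]).reshape(S * n_ch, n)
        if notch is not None:
            X = filter_data(X, notch)
        bandY = _multiband_filter(X, taps)
        for band in settings.bands:
            Y = bandY[band.name].reshape(S, n_ch, n)
            n_ep = n // epoch_samples
            ep = Y[:, :, : n_ep * epoch_samples]
            ep = ep.reshape(S, n_ch, n_ep, epoch_samples).transpose(0, 2, 1, 3)
            if settings.drop_edge_epochs:
                if n_ep < 3:
                    raise ValueError("record too short to drop edge epochs")
                ep = ep[:, 1:-1]
            Z = hilbert(np.ascontiguousarray(ep), axis=3)
            for r, z in zip(block, Z):
                phases = PhaseEpochs(band_name=band.name, fs=fs,
                                     analytic=np.ascontiguousarray(z))
                out[band.name].append(
                    subject_connectivity(phases, subject_id=r.subject_id,
                                         labels=r.montage.labels)
                )
    return out


def cohort_bc_tables(
    conn: Mapping[str, Sequence[ConnectivityMatrix]],
) -> tuple[dict[str, np.ndarray], int]:
    """Stack per-subject betweenness profiles into subjects x nodes tables.

    Also counts disconnected-graph occurrences (any zero-PLI edge severs
    the complete graph's corresponding link)."""
    tables: dict[str, np.ndarray] = {}
    disconnected = 0
    for band, mats in conn.items():
        rows = []
        for m in mats:
            off = m.values[~np.eye(m.values.shape[0], dtype=bool)]
            if np.any(off == 0):
                disconnected += 1
            rows.append(hub_profile(m).bc)
        tables[band] = np.array(rows)
    return tables, disconnected


# ---------------------------------------------------------------------------
# Statistics over a cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortStats:
    """Band-wise ANOVA, gated post hoc tests and correlations for a cohort."""

    anova: list[AnovaResult]
    posthoc: list[PosthocResult]
    correlations: list[CorrelationResult]
    gated_bands: list[str]


def group_comparison_stats(
    bc_tables: Mapping[str, np.ndarray],
    metas: Sequence[SubjectMeta],
    electrodes: Sequence[str],
    settings: StatsSettings = StatsSettings(),
) -> CohortStats:
    """The between-group arm: mixed ANOVA per band, gated post hoc t-tests,
    interest-site correlations with clinical score and age."""
    groups = [m.group for m in metas]
    anova: list[AnovaResult] = []
    for band in bc_tables:
        anova.extend(rm_anova_mixed(bc_tables[band], groups, band=band))
    fdr_across_bands(anova)

    posthoc: list[PosthocResult] = []
    gated: list[str] = []
    for band in bc_tables:
        try:
            res = posthoc_ttests(bc_tables[band], band, electrodes, anova,
                                 groups=groups, alpha=settings.alpha,
                                 q_threshold=settings.q_threshold)
        except GatingError:
            continue
        gated.append(band)
        posthoc.extend(res)

    correlations = _interest_correlations(bc_tables, metas, electrodes, settings)
    return CohortStats(anova=anova, posthoc=posthoc, correlations=correlations,
                       gated_bands=gated)


def _interest_correlations(bc_tables, metas, electrodes, settings) -> list[CorrelationResult]:
    electrodes = [str(e) for e in electrodes]
    out = []
    patients = [i for i, m in enumerate(metas) if m.group == "patient"]
    bprs = np.array([metas[i].bprs if metas[i].bprs is not None else np.nan
                     for i in patients])
    age_all = np.array([m.age if m.age is not None else np.nan for m in metas])
    for electrode, band in settings.interest_sites:
        if band not in bc_tables or electrode not in electrodes:
            continue
        j = electrodes.index(electrode)
        col = bc_tables[band][:, j]
        pv = col[patients]
        ok = ~np.isnan(bprs)
        if ok.sum() >= 3 and np.var(pv[ok]) > 0 and np.var(bprs[ok]) > 0:
            out.append(pearson_corr(pv[ok], bprs[ok],
                                    pair=f"BC@{electrode}-{band} vs BPRS (patient)"))
        oka = ~np.isnan(age_all)
        if oka.sum() >= 3 and np.var(col[oka]) > 0 and np.var(age_all[oka]) > 0:
            out.append(pearson_corr(col[oka], age_all[oka],
                                    pair=f"BC@{electrode}-{band} vs age (all)"))
    return out


def treatment_comparison_stats(
    bc_pre: Mapping[str, np.ndarray],
    bc_post: Mapping[str, np.ndarray],
    electrodes: Sequence[str],
    settings: StatsSettings = StatsSettings(),
) -> CohortStats:
    """The within-subject arm: treatment x node ANOVA per band plus gated
    paired post hoc t-tests."""
    anova: list[AnovaResult] = []
    for band in bc_pre:
        anova.extend(rm_anova_prepost(bc_pre[band], bc_post[band], band=band))
    fdr_across_bands(anova)
    posthoc: list[PosthocResult] = []
    gated: list[str] = []
    for band in bc_pre:
        try:
            res = posthoc_ttests(bc_pre[band], band, electrodes, anova,
                                 paired_post=bc_post[band], alpha=settings.alpha,
                                 q_threshold=settings.q_threshold)
        except GatingError:
            continue
        gated.append(band)
        posthoc.extend(res)
    return CohortStats(anova=anova, posthoc=posthoc, correlations=[], gated_bands=gated)


# ---------------------------------------------------------------------------
# Tidy tables
# ---------------------------------------------------------------------------

def anova_frame(anova: Sequence[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "band": a.band, "effect": a.effect, "F": a.F, "df1": a.df1, "df2": a.df2,
        "epsilon": a.epsilon, "p_unc": a.p_unc, "p_gg": a.p_gg,
        "p_fdr_bands": a.p_fdr_bands, "partial_eta_sq": a.eta_sq,
    } for a in anova])


def posthoc_frame(posthoc: Sequence[PosthocResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "band": r.band, "electrode": r.electrode, "t": r.t, "df": r.df,
        "p_raw": r.p_raw, "q_bh": r.q_bh, "direction": r.direction,
        "significant": r.significant,
    } for r in posthoc])


def correlation_frame(corrs: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": c.pair, "r": c.r, "p": c.p, "n": c.n, "significant": c.significant,
    } for c in corrs])


def bc_frame(bc_tables: Mapping[str, np.ndarray], metas: Sequence[SubjectMeta],
             electrodes: Sequence[str]) -> pd.DataFrame:
    rows = []
    for band, table in bc_tables.items():
        for m, bc_row in zip(metas, table):
            for e, v in zip(electrodes, bc_row):
                rows.append({"subject_id": m.subject_id, "band": band,
                             "electrode": e, "bc": v})
    return pd.DataFrame(rows)


def bc_tables_from_frame(df: pd.DataFrame, subject_ids: Sequence[str],
                         electrodes: Sequence[str]) -> dict[str, np.ndarray]:
    """Inverse of :func:`bc_frame`, aligned to the given subject order."""
    tables = {}
    for band, sub in df.groupby("band", sort=False):
        piv = sub.pivot(index="subject_id", columns="electrode", values="bc")
        tables[str(band)] = piv.loc[list(subject_ids), list(electrodes)].to_numpy()
    return tables


def top_edges_frame(conn: Mapping[str, Sequence[ConnectivityMatrix]],
                    metas: Sequence[SubjectMeta], electrodes: Sequence[str],
                    fraction: float) -> pd.DataFrame:
    """Strongest edges of the group-mean PLI matrix, per band and group."""
    rows = []
    groups = np.array([m.group for m in metas])
    for band, mats in conn.items():
        stack = np.stack([m.values for m in mats])
        for g in sorted(set(groups)):
            mean = stack[groups == g].mean(axis=0)
            for a, b, v in top_edges(mean, electrodes, fraction):
                rows.append({"band": band, "group": g, "electrode_a": a,
                             "electrode_b": b, "pli": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

def _load_input_cohort(config: RunConfig) -> tuple[list[EEGRecording], list[SubjectMeta]]:
    if config.simulate is not None:
        return generate_cohort(config.simulate)
    metas = read_metadata(config.metadata_path)
    recs = []
    for m in metas:
        path = None
        for suffix in (".edf", ".tsv", ".txt"):
            cand = Path(config.input_dir) / f"{m.subject_id}{suffix}"
            if cand.exists():
                path = cand
                break
        if path is None:
            raise FileNotFoundError(
                f"no recording found for subject {m.subject_id} in {config.input_dir}"
            )
        recs.append(read_recording(path))
    return recs, metas


def run_pipeline(config: RunConfig, out_dir: str | Path) -> CohortStats:
    """Execute simulate/load -> preprocess -> PLI -> hubs -> stats, persisting
    every intermediate artifact under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs, metas = _load_input_cohort(config)
    montage = recs[0].montage
    electrodes = list(montage.labels)

    conn = cohort_connectivity(recs, config.preprocess)
    pli_dir = out / "pli"
    for band, mats in conn.items():
        bdir = pli_dir / band
        bdir.mkdir(parents=True, exist_ok=True)
        for m in mats:
            write_matrix(m.values, electrodes, electrodes, bdir / f"{m.subject_id}.tsv")

    bc_tables, disconnected = cohort_bc_tables(conn)
    bc_frame(bc_tables, metas, electrodes).to_csv(out / "bc.csv", index=False)
    write_metadata(metas, out / "metadata.csv")

    stats = group_comparison_stats(bc_tables, metas, electrodes, config.stats)
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    anova_frame(stats.anova).to_csv(stats_dir / "anova.csv", index=False)
    posthoc_frame(stats.posthoc).to_csv(stats_dir / "posthoc.csv", index=False)
    correlation_frame(stats.correlations).to_csv(stats_dir / "correlations.csv", index=False)
    top_edges_frame(conn, metas, electrodes, config.stats.top_edge_fraction
                    ).to_csv(stats_dir / "top_edges.csv", index=False)

    n_samples = recs[0].n_samples
    epoch_samples = int(round(config.preprocess.epoch_len_s * recs[0].fs))
    n_epochs = n_samples // epoch_samples - (2 if config.preprocess.drop_edge_epochs else 0)
    manifest = {
        "package": "plihub",
        "version": __version__,
        "seed": config.seed,
        "n_subjects": len(recs),
        "groups": {g: sum(m.group == g for m in metas) for g in sorted({m.group for m in metas})},
        "fs": recs[0].fs,
        "duration_s": recs[0].duration_s,
        "epochs_per_band": n_epochs,
        "bands": [b.name for b in config.preprocess.bands],
        "gated_bands": stats.gated_bands,
        "disconnected_graphs": disconnected,
        "preprocess": asdict(config.preprocess),
        "stats": {"alpha": config.stats.alpha, "q_threshold": config.stats.q_threshold,
                  "top_edge_fraction": config.stats.top_edge_fraction},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return stats


def simulate_to_dir(config: CohortConfig, out_dir: str | Path, fmt: str = "edf") -> None:
    """Write a synthetic cohort as EDF (or text) recordings plus metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs, metas = generate_cohort(config)
    suffix = ".edf" if fmt == "edf" else ".tsv"
    for rec in recs:
        write_recording(rec, out / f"{rec.subject_id}{suffix}")
    write_metadata(metas, out / "metadata.csv")


def stats_from_saved(bc_csv: str | Path, metadata_csv: str | Path,
                     out_dir: str | Path,
                     settings: StatsSettings = StatsSettings()) -> CohortStats:
    """Re-run the statistics stage from persisted betweenness profiles."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metas = read_metadata(metadata_csv)
    df = pd.read_csv(bc_csv, float_precision="round_trip")
    electrodes = [e for e in DEFAULT_MONTAGE.labels if e in set(df["electrode"])]
    bc_tables = bc_tables_from_frame(df, [m.subject_id for m in metas], electrodes)
    stats = group_comparison_stats(bc_tables, metas, electrodes, settings)
    anova_frame(stats.anova).to_csv(out / "anova.csv", index=False)
    posthoc_frame(stats.posthoc).to_csv(out / "posthoc.csv", index=False)
    correlation_frame(stats.correlations).to_csv(out / "correlations.csv", index=False)
    return stats
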