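"""End-to-end run orchestration.

One configuration drives simulate -> prep -> cluster -> backfit -> stats
-> connect -> compare; every stage writes its artifacts under the run
directory and appends a line to ``log.jsonl`` (stage, wall time, seed).
Stage seeds derive from the master seed via
``numpy.random.SeedSequence([master_seed, stage_index])`` so each stage
is independently reproducible; re-running an identical configuration
reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group_analysis as ga
from . import io as mio
from . import sequence_stats as seqstats
from .connectivity import compute_state_connectivity, permutation_test
from .core import StateSequence
from .microstates import GevCurve, backfit, fit_kmeans, scan_k, select_k
from .preprocessing import bandpass, gfp_trace, sample_peaks
from .synthetic import Coupling, GroupSpec, SequenceParams, generate_cohort, make_state_maps

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_STAGES = ["simulate", "prep", "cluster", "backfit", "stats", "connect", "compare"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run (YAML round-trippable)."""

    seed: int = 0
    # cohort
    n_scans: tuple[int, int] = (27, 57)
    group_names: tuple[str, str] = ("MCS", "VS")
    k: int = 7
    n_parcels: int = 78
    duration_s: float = 600.0
    fs: float = 250.0
    dwell_mean_ms: float = 100.0
    dwell_dispersion: float = 1.0
    target_hurst: float | None = None
    dwell_multipliers: tuple[float, float] = (1.0, 1.0)
    map_max_abs_corr: float = 0.5
    noise_sd: float = 0.05
    coupling: list[dict] = field(default_factory=list)
    # prep
    band: tuple[float, float] = (1.0, 30.0)
    n_peaks: int = 5000
    # cluster
    k_range: tuple[int, int] = (2, 20)
    restarts: int = 20
    tol: float = 1e-6
    max_iter: int = 500
    kneedle_sensitivity: float = 1.0
    polarity_invariant: bool = True
    # connect
    bands: list[str] = field(default_factory=lambda: ["delta", "theta", "alpha", "beta"])
    window_s: float = 5.0
    n_perm: int = 100
    n_folds: int = 5
    classifier: str = "lda"
    # compare
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("n_scans", "group_names", "dwell_multipliers", "band", "k_range"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key in ("n_scans", "group_names", "dwell_multipliers", "band", "k_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.seed), _STAGES.index(stage)])

    def group_spec(self) -> GroupSpec:
        maps_seed = np.random.default_rng(self.stage_seed("simulate"))
        maps = make_state_maps(
            self.k, self.n_parcels, self.map_max_abs_corr, seed=maps_seed
        )
        k = self.k
        T = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(T, 0.0)
        params = SequenceParams(
            transition_matrix=T,
            dwell_mean=self.dwell_mean_ms,
            dwell_dispersion=self.dwell_dispersion,
            target_hurst=self.target_hurst,
            duration_s=self.duration_s,
            fs=self.fs,
        )
        coupling = [Coupling(**c) for c in self.coupling]
        return GroupSpec(
            n_scans=tuple(self.n_scans),
            params=params,
            maps=maps,
            group_names=tuple(self.group_names),
            dwell_multipliers=tuple(self.dwell_multipliers),
            coupling=coupling,
            noise_sd=self.noise_sd,
            seed=int(np.random.default_rng(self.stage_seed("simulate")).integers(2**31)),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _log(run_dir: Path, stage: str, t0: float, **extra) -> None:
    entry = {"stage": stage, "wall_s": round(time.time() - t0, 3), **extra}
    with open(run_dir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    spec = cfg.group_spec()
    generate_cohort(spec, out_dir=run_dir / "scans")
    _log(run_dir, "simulate", t0, n_scans=sum(cfg.n_scans))


def _scan_paths(run_dir: Path) -> list[Path]:
    manifest = mio.read_json(run_dir / "scans" / "manifest.json")
    paths = [run_dir / "scans" / f"{e['scan_id']}.tsv" for e in manifest["scans"]]
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"scan files missing: {missing[:3]}...")
    return paths


def stage_prep(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    rng = np.random.default_rng(cfg.stage_seed("prep"))
    peak_rows, peak_meta = [], []
    for path in _scan_paths(run_dir):
        ts = mio.read_scan(path)
        ts = bandpass(ts, *cfg.band)
        trace = gfp_trace(ts)
        chosen = sample_peaks(trace.peak_indices, cfg.n_peaks, rng)
        peak_rows.append(ts.data[:, chosen].T)
        peak_meta.append({"scan_id": ts.scan_id, "n_peaks": int(chosen.size)})
    pooled = np.vstack(peak_rows)
    out = run_dir / "prep"
    out.mkdir(exist_ok=True)
    np.save(out / "pooled_peak_maps.npy", pooled.astype(np.float32))
    mio.write_json({"scans": peak_meta, "pooled_rows": int(pooled.shape[0])}, out / "peaks.json")
    _log(run_dir, "prep", t0, pooled_rows=int(pooled.shape[0]))


def stage_cluster(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    pooled = np.load(run_dir / "prep" / "pooled_peak_maps.npy")
    seed = int(np.random.default_rng(cfg.stage_seed("cluster")).integers(2**31))
    curve = scan_k(
        pooled,
        k_range=tuple(cfg.k_range),
        restarts=cfg.restarts,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        seed=seed,
        polarity_invariant=cfg.polarity_invariant,
    )
    chosen_k = select_k(curve, sensitivity=cfg.kneedle_sensitivity)
    model = fit_kmeans(
        pooled,
        chosen_k,
        restarts=cfg.restarts,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        seed=np.random.default_rng(seed + 1),
        polarity_invariant=cfg.polarity_invariant,
    )
    out = run_dir / "cluster"
    out.mkdir(exist_ok=True)
    pd.DataFrame({"k": curve.k_values, "gev": curve.gev_values}).to_csv(
        out / "gev_curve.csv", index=False
    )
    mio.write_json(
        {
            "k": model.k,
            "selected_by": "kneedle",
            "maps": model.maps,
            "gev": model.gev,
            "polarity_invariant": model.polarity_invariant,
            "seed": seed,
            "fit_meta": model.fit_meta,
        },
        out / "model.json",
    )
    _log(run_dir, "cluster", t0, selected_k=chosen_k, gev=model.gev)


def _load_model(run_dir: Path):
    from .microstates import MicrostateModel

    d = mio.read_json(run_dir / "cluster" / "model.json")
    return MicrostateModel(
        maps=np.asarray(d["maps"]),
        k=int(d["k"]),
        polarity_invariant=bool(d["polarity_invariant"]),
        gev=float(d["gev"]),
        fit_meta=d.get("fit_meta", {}),
    )


def stage_backfit(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    model = _load_model(run_dir)
    out = run_dir / "sequences"
    out.mkdir(exist_ok=True)
    for path in _scan_paths(run_dir):
        ts = bandpass(mio.read_scan(path), *cfg.band)
        trace = gfp_trace(ts)
        seq = backfit(ts, model, trace)
        pd.DataFrame({"label": seq.labels}).to_csv(out / f"{ts.scan_id}.csv", index=False)
    _log(run_dir, "backfit", t0, k=model.k)


def _load_sequences(cfg: RunConfig, run_dir: Path) -> list[StateSequence]:
    manifest = mio.read_json(run_dir / "scans" / "manifest.json")
    seqs = []
    for entry in manifest["scans"]:
        labels = pd.read_csv(run_dir / "sequences" / f"{entry['scan_id']}.csv")["label"]
        seqs.append(
            StateSequence(
                labels=labels.to_numpy(),
                fs=cfg.fs,
                source="backfit",
                scan_id=entry["scan_id"],
                group=entry["group"],
            )
        )
    return seqs


def stage_stats(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    model = _load_model(run_dir)
    out = run_dir / "stats"
    out.mkdir(exist_ok=True)
    tidy, glob, syntaxes = [], [], {}
    for seq in _load_sequences(cfg, run_dir):
        st = seqstats.class_stats(seq, k=model.k)
        for c in range(model.k):
            tidy.append(
                {
                    "scan_id": seq.scan_id,
                    "group": seq.group,
                    "class": c,
                    "duration_ms": st.duration_ms[c],
                    "coverage": st.coverage[c],
                    "occurrence": st.occurrence[c],
                }
            )
        hurst = seqstats.hurst_exponent(seq, k=model.k)
        glob.append(
            {
                "scan_id": seq.scan_id,
                "group": seq.group,
                "mean_duration_ms": st.global_mean_duration_ms,
                "hurst": hurst,
                "n_runs": st.n_runs,
            }
        )
        syntaxes[seq.scan_id] = seqstats.transition_matrix(seq, k=model.k)
    pd.DataFrame(tidy).to_csv(out / "class_stats.csv", index=False)
    pd.DataFrame(glob).to_csv(out / "global_stats.csv", index=False)
    mio.write_json(
        {sid: m.probs for sid, m in syntaxes.items()}, out / "syntax_matrices.json"
    )
    _log(run_dir, "stats", t0, n_scans=len(glob))


def stage_connect(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    model = _load_model(run_dir)
    seqs = {s.scan_id: s for s in _load_sequences(cfg, run_dir)}
    seed = int(np.random.default_rng(cfg.stage_seed("connect")).integers(2**31))
    feats: dict[str, list] = {b: [] for b in cfg.bands}
    labs: dict[str, list] = {b: [] for b in cfg.bands}
    for path in _scan_paths(run_dir):
        ts = mio.read_scan(path)
        conn = compute_state_connectivity(
            ts, seqs[ts.scan_id], bands=cfg.bands, window_s=cfg.window_s
        )
        for b in cfg.bands:
            X, y = conn.features[b]
            feats[b].append(X)
            labs[b].append(y)
    out = run_dir / "connect"
    out.mkdir(exist_ok=True)
    mvpa_rows = []
    for b in cfg.bands:
        X = np.vstack(feats[b])
        y = np.concatenate(labs[b])
        res = permutation_test(
            X, y, n_perm=cfg.n_perm, n_folds=cfg.n_folds, seed=seed,
            classifier=cfg.classifier,
        )
        mvpa_rows.append(
            {"band": b, "accuracy": res.accuracy, "p_value": res.p_value,
             "n_perm": cfg.n_perm, "n_windows": int(y.size), "chance": 1.0 / model.k}
        )
    pd.DataFrame(mvpa_rows).to_csv(out / "mvpa.csv", index=False)
    mio.write_json({"seed": seed, "window_s": cfg.window_s}, out / "connect_meta.json")
    _log(run_dir, "connect", t0, bands=list(cfg.bands))


def stage_compare(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    stats_table = pd.read_csv(run_dir / "stats" / "class_stats.csv")
    out = run_dir / "compare"
    out.mkdir(exist_ok=True)
    comparison = ga.compare_cohorts(stats_table, alpha=cfg.alpha)
    comparison.to_csv(out / "class_comparison.csv", index=False)
    syntax = mio.read_json(run_dir / "stats" / "syntax_matrices.json")
    manifest = mio.read_json(run_dir / "scans" / "manifest.json")
    by_group: dict[str, list] = {g: [] for g in cfg.group_names}
    for entry in manifest["scans"]:
        by_group[entry["group"]].append(np.asarray(syntax[entry["scan_id"]]))
    syn_cmp = ga.compare_syntax(
        np.stack(by_group[cfg.group_names[0]]),
        np.stack(by_group[cfg.group_names[1]]),
        alpha=cfg.alpha,
    )
    syn_cmp.to_csv(out / "syntax_comparison.csv", index=False)
    _write_report(cfg, run_dir)
    _log(run_dir, "compare", t0)


def _write_report(cfg: RunConfig, run_dir: Path) -> None:
    lines = ["# Pipeline report", ""]
    curve = pd.read_csv(run_dir / "cluster" / "gev_curve.csv")
    model = mio.read_json(run_dir / "cluster" / "model.json")
    lines += [
        f"Selected model order: k = {model['k']} (GEV = {model['gev']:.3f})",
        "",
        "## GEV curve",
        curve.to_string(index=False),
        "",
        "## MVPA decoding of microstate identity from wPLI degree features",
        pd.read_csv(run_dir / "connect" / "mvpa.csv").to_string(index=False),
        "",
        "## Group comparison (class-wise Wilcoxon, BH-FDR per indicator)",
        pd.read_csv(run_dir / "compare" / "class_comparison.csv").to_string(index=False),
        "",
    ]
    (run_dir / "report.md").write_text("\n".join(lines))


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> Path:
    """Execute every stage in order; aborts with the failing stage named."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    stage_fns = {
        "simulate": stage_simulate,
        "prep": stage_prep,
        "cluster": stage_cluster,
        "backfit": stage_backfit,
        "stats": stage_stats,
        "connect": stage_connect,
        "compare": stage_compare,
    }
    for name in _STAGES:
        try:
            stage_fns[name](cfg, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return run_dir
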