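"""End-to-end orchestration: simulate/load → preprocess → linear → network.

`RunConfig` carries every analysis parameter with defaults matching the
reference protocol (400-ms smoothing, 0.75-Hz high-pass, 15-Hz force
filter, 1000 parallel-analysis repetitions at a 95% CI, 2 extracted
components, 5-s consistency windows).  `run_pipeline` executes all stages
per (participant, muscle) group and returns a `ResultsBundle` of tidy
tables ready for external statistics; `export_bundle`/`import_bundle`
round-trip the bundle as CSV + JSON provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import lowdim, munet, preprocess, recordings_io, synthetic

logger = logging.getLogger(__name__)

TABLE_NAMES = (
    "force_summary",
    "factorability",
    "parallel_analysis",
    "components",
    "consistency",
    "network",
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults follow the reference protocol."""

    cohort_path: str | None = None          # portable-dialect spikes CSV
    simulate: dict[str, Any] | None = None  # kwargs for synthetic.generate_cohort
    analysis_window_s: tuple[float, float] | None = None  # None: derive/full
    smoothing_window_ms: float = 400.0
    highpass_hz: float = 0.75
    force_lowpass_hz: float = 15.0
    n_components: int = 2
    pa_reps: int = 1000
    pa_alpha: float = 0.05
    pa_decimate_hz: float | None = 64.0
    mi_decimate_hz: float | None = 64.0
    consistency_window_s: float = 5.0
    xcorr_max_lag_s: float = 2.0
    methods: tuple[str, ...] = ("PCA", "FA")
    min_units: int = 2
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    force_summary: pd.DataFrame
    factorability: pd.DataFrame
    parallel_analysis: pd.DataFrame
    components: pd.DataFrame
    consistency: pd.DataFrame
    network: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}


def _resolve_cohort(
    config: RunConfig,
) -> tuple[recordings_io.CohortDataset, synthetic.SyntheticCohort | None]:
    if config.simulate is not None:
        sim = synthetic.generate_cohort(seed=config.seed, **config.simulate)
        return sim.cohort, sim
    if config.cohort_path is None:
        raise ValueError("config needs either cohort_path or a simulate block")
    return recordings_io.read_cohort_csv(config.cohort_path), None


def run_pipeline(config: RunConfig, cache_dir: str | Path | None = None) -> ResultsBundle:
    """Run every stage for every (participant, muscle) group.

    Groups with fewer than ``min_units`` matched units are skipped with a
    logged reason.  Trial selection runs only when force and target exist
    for at least 3 trials; otherwise the provided trials are taken as
    already selected.  Deterministic given ``config.seed``.
    """
    if cache_dir is not None:
        hit = Path(cache_dir) / config.config_hash()
        if (hit / "provenance.json").exists():
            logger.info("cache hit at %s", hit)
            bundle = import_bundle(hit)
            bundle.provenance["cache_hit"] = True
            return bundle

    cohort, sim = _resolve_cohort(config)
    rows: dict[str, list[dict]] = {name: [] for name in TABLE_NAMES}

    for (participant, muscle), trials in cohort.groups().items():
        n_units = len(trials[0].trains)
        if n_units < config.min_units:
            logger.info(
                "skipping %s/%s: only %d matched unit(s) (< %d)",
                participant, muscle, n_units, config.min_units,
            )
            continue
        fs = trials[0].fs

        # --- trial selection -------------------------------------------------
        with_force = [
            t for t in trials if t.force is not None and t.target is not None
        ]
        if len(with_force) >= 3:
            summaries = [
                preprocess.force_rmse(
                    t.force, t.target, fs,
                    lowpass_hz=config.force_lowpass_hz,
                    trial_index=t.trial_index,
                )
                for t in with_force
            ]
            selection = preprocess.select_post_skill_trials(summaries)
            selected = [
                t for t in trials if t.trial_index in selection.selected_indices
            ]
            for s in selection.summaries:
                rows["force_summary"].append(
                    {
                        "participant": participant, "muscle": muscle,
                        "trial": s.trial_index, "rmse": s.rmse,
                        "cov_force_pct": s.cov_force,
                        "selected": s.trial_index in selection.selected_indices,
                    }
                )
        else:
            selected = trials
            for t in trials:
                if t.force is not None and t.target is not None:
                    s = preprocess.force_rmse(
                        t.force, t.target, fs,
                        lowpass_hz=config.force_lowpass_hz,
                        trial_index=t.trial_index,
                    )
                    rows["force_summary"].append(
                        {
                            "participant": participant, "muscle": muscle,
                            "trial": s.trial_index, "rmse": s.rmse,
                            "cov_force_pct": s.cov_force, "selected": True,
                        }
                    )

        window = config.analysis_window_s
        if window is None and sim is not None:
            window = sim.analysis_window_s

        # --- per-trial analyses ----------------------------------------------
        components_by_trial: dict[str, list[lowdim.ComponentSet]] = {
            m: [] for m in config.methods
        }
        for t in selected:
            if window is None:
                end = max(
                    (int(tr.discharge_samples[-1]) + 1 for tr in t.trains
                     if tr.n_discharges), default=0,
                )
                w = (0.0, end / fs)
            else:
                w = window
            spikes = preprocess.binarize(t.trains, w[0], w[1])
            rates = preprocess.smooth_rates(spikes, config.smoothing_window_ms)
            Z = preprocess.detrend_standardize(rates, config.highpass_hz)

            report = lowdim.kmo(Z)
            rows["factorability"].append(
                {
                    "participant": participant, "muscle": muscle,
                    "trial": t.trial_index,
                    "kmo_overall": report.kmo_overall,
                    "factorable": report.factorable,
                    "n_units": n_units,
                }
            )
            pa = lowdim.parallel_analysis(
                Z,
                n_reps=config.pa_reps,
                alpha=config.pa_alpha,
                seed=_derive_seed(config.seed, participant, muscle, t.trial_index),
                decimate_to_hz=config.pa_decimate_hz,
            )
            rows["parallel_analysis"].append(
                {
                    "participant": participant, "muscle": muscle,
                    "trial": t.trial_index, "n_retain": pa.n_retain,
                    "eigenvalue_1": pa.observed_eigenvalues[0],
                    "null_upper_1": pa.null_upper[0],
                }
            )

            force_win = None
            if t.force is not None:
                f = preprocess._lowpass(t.force, fs, config.force_lowpass_hz)
                force_win = f[int(round(w[0] * fs)): int(round(w[1] * fs))]

            pca_variance = None
            for method in config.methods:
                comp = lowdim.extract_components(
                    Z, method=method, n_components=config.n_components
                )
                components_by_trial[method].append(comp)
                if method == "PCA":
                    pca_variance = comp.variance_explained_pct
                force_rs = (
                    lowdim.component_force_correlation(
                        comp, force_win, fs, config.xcorr_max_lag_s
                    )
                    if force_win is not None
                    else [None] * comp.n_components
                )
                for k in range(comp.n_components):
                    rows["components"].append(
                        {
                            "participant": participant, "muscle": muscle,
                            "trial": t.trial_index, "method": method,
                            "component": k + 1,
                            # headline variance share follows the PCA convention
                            "variance_pct": (
                                pca_variance[k] if pca_variance is not None
                                else comp.variance_explained_pct[k]
                            ),
                            "force_peak_r": (
                                force_rs[k].peak_r if force_rs[k] else np.nan
                            ),
                            "force_lag_s": (
                                force_rs[k].lag_s if force_rs[k] else np.nan
                            ),
                        }
                    )

            adj = munet.mi_matrix(Z, decimate_to_hz=config.mi_decimate_hz)
            perc = munet.percolation_threshold(adj)
            net = munet.build_network(adj, perc)
            if net.edges:
                comms = munet.link_communities(net)
                metrics = munet.network_metrics(net, comms)
            else:
                metrics = {
                    "density": 0.0, "n_edges": 0,
                    "n_components": 0, "first_component_fraction": 0.0,
                }
            rows["network"].append(
                {
                    "participant": participant, "muscle": muscle,
                    "trial": t.trial_index,
                    "mi_threshold_nats": perc.threshold,
                    **metrics,
                }
            )

        # --- across-trial consistency ----------------------------------------
        for method, comps in components_by_trial.items():
            if len(comps) < 2:
                continue
            cons = lowdim.trial_consistency(
                comps, fs,
                window_s=config.consistency_window_s,
                max_lag_s=config.xcorr_max_lag_s,
            )
            trial_ids = [t.trial_index for t in selected]
            for (i, j), vals in cons.items():
                for k, v in enumerate(vals):
                    rows["consistency"].append(
                        {
                            "participant": participant, "muscle": muscle,
                            "trial_a": trial_ids[i], "trial_b": trial_ids[j],
                            "method": method, "component": k + 1,
                            "mean_peak_r": float(v),
                        }
                    )

    bundle = ResultsBundle(
        **{name: pd.DataFrame(rows[name]) for name in TABLE_NAMES},
        provenance=_provenance(config),
    )
    if cache_dir is not None:
        export_bundle(bundle, Path(cache_dir) / config.config_hash())
    return bundle


def _derive_seed(seed: int, *parts: Any) -> int:
    blob = json.dumps([seed, *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)


def _provenance(config: RunConfig) -> dict[str, Any]:
    import scipy

    from . import __version__

    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "mupool": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "cache_hit": False,
    }


def export_bundle(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write CSV tables, provenance JSON and a log under stable names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.tables().items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = outdir / "provenance.json"
    p.write_text(json.dumps(bundle.provenance, indent=1, default=str))
    written.append(p)
    log = outdir / "run.log"
    log.write_text(
        "\n".join(
            f"{name}: {len(df)} rows" for name, df in bundle.tables().items()
        )
        + f"\nconfig_hash: {bundle.provenance.get('config_hash', '')}\n"
    )
    written.append(log)
    return written


def import_bundle(outdir: str | Path) -> ResultsBundle:
    outdir = Path(outdir)
    tables = {}
    for name in TABLE_NAMES:
        p = outdir / f"{name}.csv"
        tables[name] = pd.read_csv(p) if p.stat().st_size > 1 else pd.DataFrame()
    provenance = json.loads((outdir / "provenance.json").read_text())
    return ResultsBundle(**tables, provenance=provenance)
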