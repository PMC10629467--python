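"""End-to-end orchestration: simulate -> preprocess -> microstates ->
quantifiers -> statespace -> stats, with reproducible file outputs.

Every output table is written as CSV together with a manifest recording the
configuration hash, the seed and the package version; re-running the same
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from somnostate import __version__
from somnostate.core import DesignError
from somnostate.microstates import (
    IntervalExcluded,
    align_and_average,
    epoch_peak_maps,
    label_by_template,
    modified_kmeans,
)
from somnostate.preprocess import preprocess_set
from somnostate.quantifiers import UnlabelableEpoch, quantify_set
from somnostate.statespace import average_descriptors
from somnostate.stats import (
    RESPONSES_DESCRIPTOR,
    RESPONSES_QUANTIFIER,
    ModelSpec,
    contrast_table,
    fit_lmm,
    predicted_trajectories,
    prepare_table,
    tanova,
    channel_t_map,
)
from somnostate.synth import CohortSpec, GroupEffects, SimulationConfig, simulate_cohort
from somnostate.templates import canonical_templates

log = logging.getLogger("somnostate")


@dataclass
class PipelineConfig:
    """One JSON-serializable document driving the whole pipeline."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    band_low: float = 2.0
    band_high: float = 20.0
    suppression_threshold: float = 10.0
    n_classes: int = 4
    clustering_restarts: int = 10
    n_permutations: int = 500
    time_bin_minutes: float = 30.0
    min_datasets: int = 2
    random_slopes: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**doc)

    def to_json(self) -> str:
        def jsonable(obj):
            if isinstance(obj, dict):
                return {
                    json.dumps(list(k)) if isinstance(k, tuple) else k: jsonable(v)
                    for k, v in obj.items()
                }
            return obj

        return json.dumps(jsonable(dataclasses.asdict(self)), sort_keys=True, indent=1)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        if "group_effects" in kwargs and isinstance(kwargs["group_effects"], dict):
            ge = kwargs["group_effects"]

            def decode(d):
                return {tuple(json.loads(k)) if isinstance(k, str) else tuple(k): v
                        for k, v in d.items()}

            kwargs["group_effects"] = GroupEffects(
                duration_slope=decode(ge.get("duration_slope", {})),
                log_gain_slope=decode(ge.get("log_gain_slope", {})),
                log_snr_slope=decode(ge.get("log_snr_slope", {})),
                concentration_slope=decode(ge.get("concentration_slope", {})),
            )
        return CohortSpec(**kwargs)


def analyse_cohort(cohort, config: PipelineConfig) -> dict:
    """Run preprocessing through statistics on an in-memory cohort.

    Returns a dict of DataFrames / results keyed by stage. This is the
    library entry point used by the CLI ``run`` command and by tests.
    """
    rng = np.random.default_rng(config.seed)

    # --- preprocess -------------------------------------------------------
    processed = [
        (meta, [preprocess_set(s, config.band_low, config.band_high) for s in sets])
        for meta, sets in cohort.patients
    ]

    # --- per-set clustering ----------------------------------------------
    per_set = []       # (meta, epoch_set, solution)
    for meta, sets in processed:
        for s in sets:
            maps = np.vstack([epoch_peak_maps(e) for e in s.epochs])
            sol = modified_kmeans(
                maps, config.n_classes, restarts=config.clustering_restarts,
                seed=int(rng.integers(2**31)),
            )
            per_set.append((meta, s, sol))

    # --- hierarchical averaging: group means per (pod, time bin), grand mean
    group_means = []
    keys = sorted({(m.pod, int(s.mean_time // config.time_bin_minutes)) for m, s, _ in per_set})
    for key in keys:
        sols = [sol for m, s, sol in per_set
                if (m.pod, int(s.mean_time // config.time_bin_minutes)) == key]
        try:
            group_means.append(align_and_average(sols, min_datasets=config.min_datasets))
        except IntervalExcluded:
            log.info("time bin %s excluded (<%d datasets)", key, config.min_datasets)
    grand = align_and_average(group_means, min_datasets=1)
    grand = label_by_template(grand, canonical_templates()[: config.n_classes])

    # --- quantifiers and descriptors -------------------------------------
    quant_rows, desc_rows = [], []
    for meta, s, _ in per_set:
        try:
            q = quantify_set(s, grand, n_classes=config.n_classes)
        except UnlabelableEpoch:
            continue
        quant_rows.append(q)
        desc_rows.append(average_descriptors(s))
    quantifiers = pd.concat(quant_rows, ignore_index=True).rename(
        columns={"duration": "duration_ms"}
    )
    descriptors = pd.DataFrame(desc_rows).reset_index(drop=True)

    meta_df = pd.DataFrame(
        [dataclasses.asdict(meta) for meta, _ in processed]
    )

    # --- mixed models -----------------------------------------------------
    q_table = prepare_table(quantifiers, meta_df)
    d_table = prepare_table(descriptors, meta_df)
    models, contrasts, trajectories = {}, {}, {}
    durations_grid = np.linspace(
        float(d_table["anaesthesia_duration"].min()),
        float(d_table["anaesthesia_duration"].max()),
        25,
    )
    for resp in RESPONSES_QUANTIFIER:
        spec = ModelSpec(resp, "quantifier", random_slopes=config.random_slopes)
        try:
            res = fit_lmm(q_table, spec)
        except DesignError as err:
            log.warning("model %s skipped: %s", resp, err)
            continue
        models[resp] = res
        contrasts[resp] = contrast_table(res)
        trajectories[resp] = predicted_trajectories(res, durations_grid, q_table)
    for resp in RESPONSES_DESCRIPTOR:
        spec = ModelSpec(resp, "descriptor")
        try:
            res = fit_lmm(d_table, spec)
        except DesignError as err:
            log.warning("model %s skipped: %s", resp, err)
            continue
        models[resp] = res
        contrasts[resp] = contrast_table(res)
        trajectories[resp] = predicted_trajectories(res, durations_grid, d_table)

    # --- TANOVA on first intervals ---------------------------------------
    tanova_result, tmaps = None, None
    first_maps, pod_flags = _first_interval_maps(processed, per_set, config)
    if first_maps is not None:
        try:
            tanova_result = tanova(
                first_maps, pod_flags,
                n_permutations=config.n_permutations,
                seed=int(rng.integers(2**31)),
            )
        except DesignError as err:
            log.warning("TANOVA skipped: %s", err)
        # main-effect t-map: class-average non-suppression vs suppression
        tmaps = channel_t_map(
            first_maps[:, :, 0].mean(axis=1), first_maps[:, :, 1].mean(axis=1), paired=True
        )

    return dict(
        grand_solution=grand,
        quantifiers=quantifiers,
        descriptors=descriptors,
        metadata=meta_df,
        models=models,
        contrasts=contrasts,
        trajectories=trajectories,
        tanova=tanova_result,
        t_map=tmaps,
    )


def _first_interval_maps(processed, per_set, config: PipelineConfig):
    """Per patient: class maps of the first non-suppression and first
    suppression interval, as (subjects, classes, 2, channels). Patients
    missing either condition are excluded."""
    by_patient: dict[str, dict[bool, np.ndarray]] = {}
    pod_of: dict[str, bool] = {}
    for meta, s, sol in sorted(per_set, key=lambda t: t[1].mean_time):
        slot = by_patient.setdefault(meta.patient_id, {})
        if s.suppression not in slot:
            aligned = label_by_template(sol, canonical_templates()[: config.n_classes])
            slot[s.suppression] = aligned.maps
            pod_of[meta.patient_id] = meta.pod
    complete = [pid for pid, slot in by_patient.items() if len(slot) == 2]
    if len(complete) < 4:
        return None, None
    maps = np.stack([
        np.stack([by_patient[pid][False], by_patient[pid][True]], axis=1)
        for pid in complete
    ])
    pod = np.array([pod_of[pid] for pid in complete])
    return maps, pod


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort per the configuration, analyse it, write the report.

    Outputs: quantifier/descriptor/metadata CSVs, coefficient, contrast and
    trajectory CSVs per response, a TANOVA JSON report, the grand-mean class
    maps as CSV, and ``manifest.json`` with the config hash and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("running")
    try:
        cohort = simulate_cohort(config.simulation_config(), config.cohort_spec())
        results = analyse_cohort(cohort, config)

        float_fmt = "%.10g"
        results["quantifiers"].to_csv(out / "quantifiers.csv", index=False, float_format=float_fmt)
        results["descriptors"].to_csv(out / "descriptors.csv", index=False, float_format=float_fmt)
        results["metadata"].to_csv(out / "metadata.csv", index=False, float_format=float_fmt)
        grand = results["grand_solution"]
        pd.DataFrame(grand.maps.T, columns=list(grand.labels)).to_csv(
            out / "grand_mean_maps.csv", index=False, float_format=float_fmt
        )
        for resp, model in results["models"].items():
            model.coefficients.to_csv(out / f"coefficients_{resp}.csv", float_format=float_fmt)
            results["contrasts"][resp].to_csv(
                out / f"contrasts_{resp}.csv", index=False, float_format=float_fmt
            )
            results["trajectories"][resp].to_csv(
                out / f"trajectories_{resp}.csv", index=False, float_format=float_fmt
            )
        report = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "version": __version__,
            "n_patients": len(cohort.patients),
            "n_intervals": int(
                results["descriptors"].shape[0]
            ),
            "grand_labels": list(grand.labels),
            "template_correlations": [float(x) for x in grand.template_correlations],
        }
        if results["tanova"] is not None:
            report["tanova"] = results["tanova"].table.to_dict(orient="records")
        if results["t_map"] is not None:
            report["t_map_suppression_main_effect"] = [float(t) for t in results["t_map"]]
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        manifest = {
            "config_hash": config.config_hash,
            "config": json.loads(config.to_json()),
            "version": __version__,
            "outputs": sorted(p.name for p in out.glob("*.csv")) + ["report.json"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception:
        log.exception("pipeline failed; partial outputs retained under %s", out)
        raise
    marker.unlink()
    return results
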