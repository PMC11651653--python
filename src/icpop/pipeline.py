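"""End-to-end pipeline: simulate -> preprocess -> score -> modulate ->
cluster -> decode -> compare, as configured, logged, hash-manifested stages.

A run directory holds one sub-directory per session bundle plus the
cross-session tables; ``manifest.json`` records a SHA-256 per artifact so
a rerun with the same config and seed can be checked for reproducibility.
Stages communicate only through the declared file formats (HDF5 for
matrices, CSV for tables).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior, clustering, decoding, groupstats, modulation, signals, synthdata

log = logging.getLogger(__name__)

__all__ = ["default_config", "validate_config", "run", "report"]


def default_config() -> dict:
    """A small but complete pipeline configuration (two sessions)."""
    return {
        "seed": 0,
        "sessions": [
            {"id": "s01", "group": "non-lesioned", "n_neurons": 20},
            {"id": "s02", "group": "lesioned", "n_neurons": 20},
        ],
        "schedule": dataclasses.asdict(synthdata.ScheduleParams(n_trials=150)),
        "psych": dataclasses.asdict(synthdata.PsychModel()),
        "synth": {"noise_sd": 0.05, "neuropil_gain": 0.7, "frame_rate_hz": 28.0},
        "signals": {
            "neuropil_coefficient": 0.7,
            "gaussian_sigma_s": 10.0,
            "min_window_s": 60.0,
            "max_window_s": 60.0,
            "L": 193,
        },
        "modulation": {"q": 0.05},
        "clustering": {
            "n_components": 9,
            "n_neighbors_grid": [5, 10, 15],
            "n_clusters_grid": [2, 3, 4, 5, 6, 7, 8],
        },
        "decoding": {"n_search": 10, "frame_stride": 4, "dummy_repeats": 50},
        "compare": {"bin_factor": 1},
    }


def validate_config(config: dict) -> tuple[synthdata.ScheduleParams, synthdata.PsychModel]:
    """Validate every stage's parameters before any stage runs.

    Dataclass constructors enforce the module preconditions; a bad field
    raises ``ValueError`` naming it before anything is written.
    """
    try:
        sched = synthdata.ScheduleParams(
            **{k: tuple(v) if k == "sound_levels" else v for k, v in config["schedule"].items()}
        )
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid schedule config: {e}") from e
    try:
        psych_cfg = dict(config["psych"])
        psych = synthdata.PsychModel(**psych_cfg)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid psych config: {e}") from e
    if not config.get("sessions"):
        raise ValueError("config lists no sessions")
    dec = config.get("decoding", {})
    decoding.DecoderConfig(
        n_search=dec.get("n_search", 25),
        frame_stride=dec.get("frame_stride", 1),
        dummy_repeats=dec.get("dummy_repeats", 100),
    )
    return sched, psych


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _decoder_config(config: dict) -> decoding.DecoderConfig:
    dec = config.get("decoding", {})
    return decoding.DecoderConfig(
        n_search=dec.get("n_search", 25),
        frame_stride=dec.get("frame_stride", 1),
        dummy_repeats=dec.get("dummy_repeats", 100),
    )


def run(config: dict, out_dir: str | Path) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Aborts on the first failing stage, naming it; outputs of completed
    stages are preserved.
    """
    sched_params, psych = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config))
    master = np.random.SeedSequence(config.get("seed", 0))
    all_seeds = master.generate_state(len(config["sessions"]) * 4 + 1) % (2**31)
    sess_seeds, cluster_seed = all_seeds[:-1], int(all_seeds[-1])
    sig_cfg = config.get("signals", {})
    L = sig_cfg.get("L", 193)
    dec_cfg = _decoder_config(config)

    stage = "simulate"
    per_session = []
    try:
        for si, sess in enumerate(config["sessions"]):
            s0, s1, s2, s3 = (int(x) for x in sess_seeds[4 * si : 4 * si + 4])
            schedule = synthdata.sample_schedule(sched_params, seed=s0)
            licks = synthdata.sample_behavior(schedule, psych, seed=s1)
            rec, truth = synthdata.synthesize_session(
                schedule,
                licks,
                synthdata.default_prototypes(),
                n_neurons=sess.get("n_neurons", 20),
                noise_sd=config["synth"].get("noise_sd", 0.05),
                neuropil_gain=config["synth"].get("neuropil_gain", 0.7),
                frame_rate_hz=config["synth"].get("frame_rate_hz", 28.0),
                seed=s2,
                session_id=sess["id"],
                group=sess.get("group", "non-lesioned"),
            )
            bundle = synthdata.write_session_bundle(
                out / "sessions" / sess["id"], rec, schedule, licks, truth
            )
            per_session.append(
                {"sess": sess, "bundle": bundle, "seed_mod": s3, "schedule": schedule, "licks": licks}
            )

        stage = "preprocess"
        for item in per_session:
            rec, schedule, licks = synthdata.read_session_bundle(item["bundle"])
            corrected = signals.neuropil_correct(
                rec.F, rec.Fneu, r=sig_cfg.get("neuropil_coefficient", 0.7)
            )
            dff = signals.compute_dff(corrected, rec.frame_rate)
            dff = signals.remove_slow_baseline(
                dff,
                gaussian_sigma_s=sig_cfg.get("gaussian_sigma_s", 10.0),
                min_window_s=sig_cfg.get("min_window_s", 60.0),
                max_window_s=sig_cfg.get("max_window_s", 60.0),
            )
            tensor = signals.extract_trials(dff, schedule)
            with h5py.File(item["bundle"] / "tensor.h5", "w") as f:
                d = f.create_dataset("tensor", data=tensor.values, track_times=False)
                f.create_dataset("dff", data=dff.values, track_times=False)
                d.attrs["window"] = json.dumps(list(tensor.window))
                d.attrs["onset_frame_index"] = tensor.onset_frame_index
                d.attrs["frame_rate"] = tensor.frame_rate
                d.attrs["trial_indices"] = json.dumps(tensor.trial_indices.tolist())
            item["tensor"], item["rec"] = tensor, rec

        stage = "behavior"
        rows = []
        for item in per_session:
            schedule, licks = item["schedule"], item["licks"]
            outcomes = behavior.score_trials(
                schedule, licks, response_window=schedule.attrs.get("response_window_s", 1.5)
            )
            summ = behavior.psychometric(outcomes)
            rows.append(summ.to_row(item["sess"]["id"]))
            item["outcomes"], item["summary"] = outcomes, summ
        pd.concat(rows, ignore_index=True).to_csv(out / "behavior_summary.csv", index=False)

        stage = "modulate"
        mod_rows = []
        for item in per_session:
            res = modulation.analyze_session(
                item["tensor"],
                item["outcomes"],
                seed=item["seed_mod"],
                q=config.get("modulation", {}).get("q", 0.05),
            )
            t = res.table.copy()
            t.insert(0, "session_id", item["sess"]["id"])
            mod_rows.append(t)
        pd.concat(mod_rows, ignore_index=True).to_csv(out / "modulation.csv", index=False)

        stage = "cluster"
        averages, sess_of_neuron, group_of_neuron = [], [], []
        for item in per_session:
            keep = signals.exclude_lick_contaminated_hits(item["outcomes"], item["licks"])
            tensor = item["tensor"]
            kept_rows = keep[tensor.trial_indices]
            sub = signals.TrialTensor(
                values=tensor.values[kept_rows],
                frame_rate=tensor.frame_rate,
                window=tensor.window,
                onset_frame_index=tensor.onset_frame_index,
                trial_indices=tensor.trial_indices[kept_rows],
            )
            try:
                avg = signals.outcome_averages(sub, item["outcomes"], L=L)
            except ValueError as e:
                log.warning("cluster: session %s skipped (%s)", item["sess"]["id"], e)
                continue
            averages.append(avg)
            n = avg.hit_avg.shape[0]
            sess_of_neuron += [item["sess"]["id"]] * n
            group_of_neuron += [item["sess"].get("group", "non-lesioned")] * n
            item["keep_mask"] = keep
        X = clustering.build_features(averages)
        clu_cfg = config.get("clustering", {})
        model = clustering.hyperparameter_search(
            X,
            n_neighbors_grid=tuple(clu_cfg.get("n_neighbors_grid", (5, 10, 15))),
            n_clusters_grid=tuple(clu_cfg.get("n_clusters_grid", range(2, 9))),
            n_components=clu_cfg.get("n_components", 9),
            seed=cluster_seed,
        )
        model.labels_frame(sess_of_neuron, group_of_neuron).to_csv(
            out / "clusters.csv", index=False
        )
        model.grid.to_csv(out / "grid_search.csv", index=False)
        prof_rows = []
        for c in np.unique(model.labels):
            in_c = model.labels == c
            hit = np.vstack([a.hit_avg for a in averages])[in_c].mean(axis=0)
            miss = np.vstack([a.miss_avg for a in averages])[in_c].mean(axis=0)
            prof_rows.append([c, "hit", *hit])
            prof_rows.append([c, "miss", *miss])
        pd.DataFrame(
            prof_rows, columns=["cluster_id", "outcome", *[f"f{i}" for i in range(L)]]
        ).to_csv(out / "cluster_profiles.csv", index=False)
        lesioned_flags = np.array([g != "non-lesioned" for g in group_of_neuron])
        if lesioned_flags.any() and not lesioned_flags.all():
            clustering.composition_test(model.labels, lesioned_flags).to_csv(
                out / "cluster_composition.csv", index=False
            )

        stage = "decode"
        results = []
        dec_rows = []
        for item in per_session:
            outcomes, tensor = item["outcomes"], item["tensor"]
            keep = item.get("keep_mask")
            if keep is None:
                keep = signals.exclude_lick_contaminated_hits(outcomes, item["licks"])
            try:
                mask, sel_levels = decoding.select_trials(outcomes, keep_mask=keep)
            except ValueError as e:
                log.warning("decode: session %s excluded (%s)", item["sess"]["id"], e)
                continue
            kept_rows = mask[tensor.trial_indices]
            labels = (outcomes["label"].to_numpy()[tensor.trial_indices][kept_rows] == "hit").astype(int)
            sub = signals.TrialTensor(
                values=tensor.values[kept_rows],
                frame_rate=tensor.frame_rate,
                window=tensor.window,
                onset_frame_index=tensor.onset_frame_index,
                trial_indices=tensor.trial_indices[kept_rows],
            )
            if not decoding.session_gate(int(labels.sum()), int((1 - labels).sum())):
                log.warning("decode: session %s failed the 15/15 gate", item["sess"]["id"])
                continue
            res = decoding.decode_session(
                sub,
                labels,
                seed=item["seed_mod"] + 1,
                config=dec_cfg,
                session_id=item["sess"]["id"],
                group=item["sess"].get("group", "non-lesioned"),
                selected_levels=sel_levels,
            )
            results.append(res)
            with h5py.File(item["bundle"] / "decoding.h5", "w") as f:
                f.create_dataset("trained_folds", data=res.trained_folds, track_times=False)
                f.create_dataset("dummy", data=res.dummy, track_times=False)
                f.create_dataset("frame_times", data=res.frame_times, track_times=False)
            row = {
                "session_id": res.session_id,
                "group": res.group,
                "n_rois": res.n_rois,
                "n_hit": res.n_hit,
                "n_miss": res.n_miss,
            }
            for lo in np.arange(-2.0, 5.0):
                row[f"acc_{lo:+.0f}s"] = res.windowed_mean(lo, lo + 1.0)
            dec_rows.append(row)
        if dec_rows:
            pd.DataFrame(dec_rows).to_csv(out / "decoding_summary.csv", index=False)

        stage = "compare"
        if len(results) >= 5:
            target = min(r.trained.size for r in results)
            trained = np.vstack(
                [decoding.interpolate_timecourse(r.trained, target) for r in results]
            )
            dummy = np.vstack([decoding.interpolate_timecourse(r.dummy, target) for r in results])
            times = decoding.interpolate_timecourse(results[0].frame_times, target)
            comp = groupstats.compare_to_dummy(trained, dummy, times)
            comp.table.assign(comparison=comp.comparison).to_csv(
                out / "comparisons.csv", index=False
            )
        else:
            log.info("compare: skipped (%d decodable sessions < 5)", len(results))
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables of a completed run.

    Returns the psychometric table, the cluster profile + composition
    tables, and the decoding timecourse table (with significance rows when
    the comparison stage ran). Raises listing any absent required artifact.
    """
    run_dir = Path(run_dir)
    required = ["behavior_summary.csv", "clusters.csv", "cluster_profiles.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"run incomplete; missing artifacts: {missing}")
    tables = {
        "psychometric": pd.read_csv(run_dir / "behavior_summary.csv"),
        "cluster_profiles": pd.read_csv(run_dir / "cluster_profiles.csv"),
    }
    comp = run_dir / "cluster_composition.csv"
    if comp.exists():
        tables["cluster_composition"] = pd.read_csv(comp)
    dec = run_dir / "decoding_summary.csv"
    if dec.exists():
        tables["decoding"] = pd.read_csv(dec)
    sig = run_dir / "comparisons.csv"
    if sig.exists():
        tables["comparisons"] = pd.read_csv(sig)
    return tables
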