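"""End-to-end orchestration of the synthetic study.

``run_study`` drives design -> synthesis -> preprocessing -> transfer
decoding (four training conditions) -> cluster statistics (single
condition, words vs. nonwords, CV vs. VC positional overlap) -> effective
connectivity on the word-trained decoding ROIs, writing every stage's
table to the output directory together with a manifest (seeds, config
hash, timings, versions) that makes the run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cluster import (ClusterRecord, between_condition_clusters,
                      bonferroni_gate, single_condition_clusters)
from .connectivity import run_connectivity
from .decode import CONDITIONS, decode_study
from .design import DesignConfig, build_stimulus_set, make_schedule
from .io import (clusters_to_frame, gc_results_to_frame, save_decoding_h5,
                 save_epochs_h5)
from .preprocess import preprocess
from .synth import GroundTruth, mark_behavioral_errors, simulate_subject

__all__ = ["AnalysisParams", "run_study", "report"]


@dataclass
class AnalysisParams:
    """Tunable analysis-stage parameters (defaults match the full design)."""

    n_assignments: int = 100
    bin_size: int = 8
    decode_step_ms: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    bonferroni_rois: int | None = None     # default: the config's ROI count
    error_rate_words: float = 0.08
    error_rate_nonwords: float = 0.14
    gc_window: tuple[float, float] = (250.0, 550.0)
    gc_order: int = 5
    gc_adapt_const: float = 0.02
    gc_downsample: int = 4
    gc_err_smooth: float = 0.5
    gc_surrogates: int = 200
    control_pair: tuple[int, int] | None = None   # default: last two ROIs
    save_epochs: bool = False


def _config_hash(config: DesignConfig, truth: GroundTruth,
                 params: AnalysisParams) -> str:
    h = hashlib.sha256()
    h.update(yaml.safe_dump(asdict(config), sort_keys=True).encode())
    for arr in (truth.segmental_amp, truth.lexical_amp, truth.slot_patterns,
                truth.item_patterns, truth.lex_patterns):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(json.dumps(
        [truth.segmental_window, truth.lexical_window, truth.noise_sd,
         truth.ar1_rho, truth.subject_jitter_sd, truth.talker_offset_sd,
         truth.amp_mod_sd, truth.amp_mod_rho,
         [astuple_edge(e) for e in truth.coupling_edges], truth.seed]).encode())
    h.update(json.dumps(asdict(params), default=list, sort_keys=True).encode())
    return h.hexdigest()


def astuple_edge(e) -> list:
    return [e.source_roi, e.target_roi, e.lag_ms, e.gain]


def run_study(
    config: DesignConfig,
    truth: GroundTruth,
    seed: int,
    outdir,
    params: AnalysisParams | None = None,
) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    params = params or AnalysisParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config, truth, params),
        "stages": {},
        "outputs": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)

        return done

    # ---- design ----------------------------------------------------------
    end = stage("design")
    items = build_stimulus_set(config)
    schedule = make_schedule(config, seed)
    schedule.to_csv(outdir / "schedule.tsv", sep="\t", index=False)
    manifest["outputs"]["schedule"] = "schedule.tsv"
    manifest["stages"]["design"] = {"seed": seed, "n_trials": len(schedule)}
    end()

    # ---- synthesis + preprocessing --------------------------------------
    end = stage("synthesis")
    epochs = {}
    for s in sorted(schedule["subject_id"].unique()):
        ep = simulate_subject(schedule, truth, config, int(s))
        ep = mark_behavioral_errors(ep, params.error_rate_words,
                                    params.error_rate_nonwords, seed=seed + 1)
        epochs[int(s)] = preprocess(ep)
    if params.save_epochs:
        save_epochs_h5(outdir / "epochs.h5", epochs)
        manifest["outputs"]["epochs"] = "epochs.h5"
    manifest["stages"]["synthesis"] = {
        "truth_seed": truth.seed, "error_seed": seed + 1,
        "n_subjects": len(epochs),
    }
    end()

    # ---- decoding --------------------------------------------------------
    end = stage("decoding")
    step = max(1, int(round(params.decode_step_ms * config.sample_rate / 1000.0)))
    tidx = np.arange(0, config.n_timepoints, step)
    dec = decode_study(
        epochs, items, CONDITIONS, n_assignments=params.n_assignments,
        bin_size=params.bin_size, seed=seed + 2, time_indices=tidx,
    )
    save_decoding_h5(outdir / "accuracy.h5", dec)
    mean_acc = dec.accuracy.mean(axis=0)        # (R, C, T)
    manifest["outputs"]["accuracy"] = "accuracy.h5"
    manifest["stages"]["decoding"] = {
        "seed": seed + 2, "n_assignments": params.n_assignments,
        "n_timepoints": int(tidx.size),
    }
    end()

    # ---- cluster statistics ---------------------------------------------
    end = stage("clusters")
    n_fam = params.bonferroni_rois or config.n_rois
    records: list[ClusterRecord] = []
    for ci, cond in enumerate(dec.conditions):
        for roi in range(config.n_rois):
            records.extend(single_condition_clusters(
                dec.accuracy[:, roi, ci, :], dec.times, roi=roi,
                condition=cond, n_perm=params.n_perm, seed=seed + 3,
                alpha=params.alpha,
            ))
    for contrast in (("words_only", "nonwords_only"),
                     ("cv_overlap", "vc_overlap")):
        ia, ib = dec.conditions.index(contrast[0]), dec.conditions.index(contrast[1])
        for roi in range(config.n_rois):
            rec_ab, rec_ba = between_condition_clusters(
                dec.accuracy[:, roi, ia, :], dec.accuracy[:, roi, ib, :],
                dec.times, roi=roi, condition_pair=contrast,
                n_perm=params.n_perm, seed=seed + 4, alpha=params.alpha,
            )
            records.extend(rec_ab)
            records.extend(rec_ba)
    flags = bonferroni_gate([r.p_value for r in records], n_rois=n_fam,
                            alpha=params.alpha) if records else []
    for r, f in zip(records, flags):
        r.significant = bool(f)
    clusters_to_frame(records).to_csv(outdir / "clusters.tsv", sep="\t",
                                      index=False)
    manifest["outputs"]["clusters"] = "clusters.tsv"
    manifest["stages"]["clusters"] = {
        "seed_single": seed + 3, "seed_between": seed + 4,
        "n_perm": params.n_perm, "bonferroni_family": n_fam,
    }
    end()

    # ---- connectivity ----------------------------------------------------
    end = stage("connectivity")
    wi = dec.conditions.index("words_only")
    decoding_rois = sorted({
        r.roi for r in records
        if r.condition == "words_only" and r.significant
    })
    gc_results = []
    if len(decoding_rois) >= 2:
        control = params.control_pair or (config.n_rois - 2, config.n_rois - 1)
        gc_results = run_connectivity(
            epochs, dec.accuracy[:, :, wi, :], dec.times, decoding_rois,
            control, window=params.gc_window, order=params.gc_order,
            adapt_const=params.gc_adapt_const,
            downsample=params.gc_downsample,
            n_surrogates=params.gc_surrogates, alpha=params.alpha,
            seed=seed + 5, err_smooth=params.gc_err_smooth,
        )
    gc_results_to_frame(gc_results).to_csv(outdir / "gc.tsv", sep="\t",
                                           index=False)
    manifest["outputs"]["gc"] = "gc.tsv"
    manifest["stages"]["connectivity"] = {
        "seed": seed + 5, "decoding_rois": decoding_rois,
        "n_surrogates": params.gc_surrogates,
    }
    end()

    manifest["timings_s"] = timings
    results = {
        "conditions": list(dec.conditions),
        "clusters": records,
        "gc": gc_results,
        "decoding_rois": decoding_rois,
        "mean_accuracy": mean_acc,
    }
    (outdir / "report.txt").write_text(report(results))
    manifest["outputs"]["report"] = "report.txt"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["results"] = results
    return manifest


def report(results: dict) -> str:
    """Human-readable summary of clusters per ROI/condition and the GC graph."""
    for key in ("conditions", "clusters", "gc"):
        if key not in results:
            raise ValueError(f"missing stage output {key!r}")
    lines = ["Synthetic lexical-decision study: summary", "=" * 42, ""]
    clusters = results["clusters"]
    sig = [r for r in clusters if r.significant]
    lines.append("Decoding clusters (Bonferroni-gated)")
    lines.append("-" * 36)
    if not sig:
        lines.append("no significant clusters")
    else:
        for cond in results["conditions"]:
            for r in sorted((x for x in sig if x.condition == cond),
                            key=lambda x: (x.roi, x.start_ms)):
                lines.append(
                    f"  {cond:>14s}  ROI {r.roi:2d}  "
                    f"{r.start_ms:6.0f}-{r.end_ms:6.0f} ms  "
                    f"size {r.size:4d}  p={r.p_value:.4g}"
                )
        for r in sorted((x for x in sig if ">" in x.condition),
                        key=lambda x: (x.condition, x.roi, x.start_ms)):
            lines.append(
                f"  {r.condition:>24s}  ROI {r.roi:2d}  "
                f"{r.start_ms:6.0f}-{r.end_ms:6.0f} ms  size {r.size:4d}  "
                f"p={r.p_value:.4g}"
            )
    lines.append("")
    lines.append("Effective connectivity (FDR-gated binomial vs. control)")
    lines.append("-" * 55)
    gc_sig = [g for g in results["gc"] if g.fdr_significant]
    if not gc_sig:
        lines.append("no significant directed interactions")
    else:
        for g in gc_sig:
            tag = "reciprocal" if g.reciprocal else "one-way"
            lines.append(
                f"  ROI {g.source_roi} -> ROI {g.target_roi}  "
                f"{g.sig_count}/{g.window_len} significant timepoints  "
                f"p={g.binomial_p:.4g}  [{tag}]"
            )
    lines.append("")
    return "\n".join(lines)
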