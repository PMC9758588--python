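"""End-to-end pipeline: simulate -> synthesize epochs -> analyze -> infer.

The pipeline mirrors the study structure: two between-participant groups
(full vs partial control), each participant performing a self-controlled and
a yoked (replay-of-own-sequences) session on the same choice problems. All
artifacts are written as TSV/JSON (epochs optionally as HDF5) with the seed
and config hash embedded.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import replay_yoked, simulate_session
from .behavior import participant_summary
from .config import RunConfig, config_hash, stage_rng
from .design import build_session
from .epochs import generate_epochs, smooth_erp
from .erp import baseline_correct, cpp_by_window, lateralized_vep
from .rsa import (
    erp_rdm_timecourse,
    frequency_rdm,
    model_rdm,
    neurometric_fit,
    orthogonalize_model,
    rsa_timecourse,
    value_frequencies,
    window_average_rdm,
)
from .stats import cluster_test_1samp, cluster_test_interaction, mixed_anova_2x2

__all__ = ["run_pipeline", "simulate_cohort", "analyze_participant_epochs"]

GROUPS = ("full", "partial")


def simulate_cohort(config: RunConfig) -> dict:
    """Simulate all trials: {(participant, condition): [TrialRecord, ...]}.

    Participants 0..n-1 are the full-control group, n..2n-1 the partial
    group; each is yoked to their own recorded sequences.
    """
    trials = {}
    for g, condition in enumerate(GROUPS):
        for i in range(config.n_per_group):
            participant = g * config.n_per_group + i
            session = build_session(
                config.design.n_trials,
                config.design.n_blocks,
                rng_seed=int(
                    stage_rng(config.seed, "design", participant).integers(2**31)
                ),
                ev_diff=config.design.ev_diff,
            )
            rng = stage_rng(config.seed, "agent", participant)
            own = simulate_session(
                config.agent, session, condition, rng, participant=participant
            )
            yoked = replay_yoked(own, config.agent, rng)
            trials[(participant, condition)] = own
            trials[(participant, yoked[0].condition)] = yoked
    return trials


def analyze_participant_epochs(epochs, config: RunConfig) -> dict:
    """Per-participant/condition EEG analysis bundle."""
    from .epochs import value_mean_epochs

    epochs = baseline_correct(epochs)
    vep = lateralized_vep(epochs)
    cpp = cpp_by_window(epochs, min_samples=config.analysis.min_samples_per_trial)

    freq = frequency_rdm(value_frequencies(epochs.events))
    dist_model = orthogonalize_model(model_rdm("distance"), freq)
    ext_model = orthogonalize_model(model_rdm("extremity"), freq)

    # RSA acts through the per-value means; collapse before smoothing
    smoothed = smooth_erp(value_mean_epochs(epochs), config.analysis.smoothing_hwhm_ms)
    rdms = erp_rdm_timecourse(smoothed)
    r_distance = rsa_timecourse(rdms, dist_model)
    r_extremity = rsa_timecourse(rdms, ext_model)

    halves = {}
    for half in ("first", "second"):
        sub = epochs.subset(epochs.events["half"].to_numpy() == half)
        try:
            half_means = smooth_erp(
                value_mean_epochs(sub), config.analysis.smoothing_hwhm_ms
            )
            halves[half] = rsa_timecourse(erp_rdm_timecourse(half_means), dist_model)
        except ValueError:
            halves[half] = np.full(len(smoothed.times), np.nan)

    window_rdm = window_average_rdm(rdms, smoothed.times, *config.analysis.rsa_window)
    nmap = neurometric_fit(window_rdm, freq)
    return {
        "p1": vep.p1_mean,
        "n1": vep.n1_mean,
        "cpp_early": cpp.early,
        "cpp_mid": cpp.mid,
        "cpp_late": cpp.late,
        "cpp_late_minus_early": cpp.late_minus_early,
        "r_distance": r_distance,
        "r_extremity": r_extremity,
        "r_distance_first_half": halves["first"],
        "r_distance_second_half": halves["second"],
        "argmax_k": nmap.argmax_k,
        "argmax_b": nmap.argmax_b,
        "times": smoothed.times,
    }


def _anova_dict(res) -> dict:
    out = {}
    for name in ("within", "between", "interaction"):
        eff = getattr(res, name)
        out[name] = None if eff is None else asdict(eff)
    return out


def _cluster_dict(res) -> dict:
    return {
        "clusters": [
            {"t_start": c.t_start, "t_end": c.t_end, "mass": c.mass, "p": p}
            for c, p in zip(res.clusters, res.p_values)
        ],
        "n_permutations": res.n_permutations,
        "threshold_p": res.threshold_p,
    }


def run_pipeline(config: RunConfig, write_epochs: bool = False) -> dict:
    """Run the full pipeline and write the report bundle to
    ``config.output_dir``. Returns the report dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "version": __version__,
    }

    trials = simulate_cohort(config)

    from .agents import trials_to_frame

    behav_frames = [trials_to_frame(t) for t in trials.values()]
    behav = pd.concat(behav_frames, ignore_index=True)
    behav.to_csv(out / "behavior.tsv", sep="\t", index=False)

    summary = participant_summary(trials)
    summary.to_csv(out / "behavior_summary.tsv", sep="\t", index=False)

    erp_rows, rsa_store = [], {}
    for (participant, condition), trial_list in sorted(trials.items()):
        rng = stage_rng(config.seed, f"epochs_{condition}", participant)
        epochs = generate_epochs(config.gen, trial_list, rng)
        if write_epochs:
            from .epochs import save_epochs_h5

            save_epochs_h5(
                epochs,
                out / f"epochs_sub{participant:02d}_{condition}.h5",
                out / f"epochs_sub{participant:02d}_{condition}_events.tsv",
            )
        res = analyze_participant_epochs(epochs, config)
        erp_rows.append(
            {
                "participant": participant,
                "condition": condition,
                "p1_mean": res["p1"],
                "n1_mean": res["n1"],
                "cpp_early": res["cpp_early"],
                "cpp_mid": res["cpp_mid"],
                "cpp_late": res["cpp_late"],
                "cpp_late_minus_early": res["cpp_late_minus_early"],
                "argmax_k": res["argmax_k"],
                "argmax_b": res["argmax_b"],
            }
        )
        rsa_store[(participant, condition)] = res

    erp_table = pd.DataFrame(erp_rows)
    erp_table.to_csv(out / "erp_summary.tsv", sep="\t", index=False)

    rsa_rows = []
    for (participant, condition), res in sorted(rsa_store.items()):
        for model_name in ("r_distance", "r_extremity"):
            for t, r in zip(res["times"], res[model_name]):
                rsa_rows.append(
                    {
                        "participant": participant,
                        "condition": condition,
                        "model": model_name[2:],
                        "time": t,
                        "r": r,
                    }
                )
    pd.DataFrame(rsa_rows).to_csv(out / "rsa_timecourses.tsv", sep="\t", index=False)

    # group statistics
    n = config.n_per_group
    group_of = lambda p: "full" if p < n else "partial"
    yoked_of = lambda c: f"yoked_{c}"

    def _within_table(metric_frame, value_col):
        """(n_participants, 2) [yoked, self] score table + group labels."""
        scores, groups = [], []
        for p in sorted(metric_frame["participant"].unique()):
            g = group_of(p)
            rows = metric_frame[metric_frame["participant"] == p]
            self_v = rows.loc[rows["condition"] == g, value_col].iloc[0]
            yoked_v = rows.loc[rows["condition"] == yoked_of(g), value_col].iloc[0]
            scores.append([yoked_v, self_v])
            groups.append(g)
        return np.array(scores), np.array(groups)

    report = dict(meta)
    report["anova"] = {}
    for metric, frame, col in (
        ("accuracy", summary, "accuracy"),
        ("recency", summary, "recency"),
        ("p1", erp_table, "p1_mean"),
        ("n1", erp_table, "n1_mean"),
        ("cpp_late_minus_early", erp_table, "cpp_late_minus_early"),
    ):
        scores, groups = _within_table(frame, col)
        if np.any(~np.isfinite(scores)):
            report["anova"][metric] = None
            continue
        report["anova"][metric] = _anova_dict(mixed_anova_2x2(scores, groups))

    # RSA cluster statistics: pooled distance effect and the 2x2 interaction
    times = next(iter(rsa_store.values()))["times"]
    participants = sorted({p for p, _ in rsa_store})
    pooled = np.stack(
        [
            np.nanmean(
                [rsa_store[(p, c)]["r_distance"] for c in
                 (group_of(p), yoked_of(group_of(p)))],
                axis=0,
            )
            for p in participants
        ]
    )
    diffs = np.stack(
        [
            rsa_store[(p, group_of(p))]["r_distance"]
            - rsa_store[(p, yoked_of(group_of(p)))]["r_distance"]
            for p in participants
        ]
    )
    groups = np.array([group_of(p) for p in participants])
    rng = stage_rng(config.seed, "cluster_stats")
    report["rsa_distance_vs_zero"] = _cluster_dict(
        cluster_test_1samp(
            pooled,
            threshold_p=config.analysis.cluster_threshold_p,
            n_perm=config.analysis.n_permutations,
            rng=rng,
            times=times,
        )
    )
    report["rsa_distance_interaction"] = _cluster_dict(
        cluster_test_interaction(
            diffs,
            groups,
            threshold_p=config.analysis.cluster_threshold_p,
            n_perm=config.analysis.n_permutations,
            rng=rng,
            times=times,
        )
    )

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    return report
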