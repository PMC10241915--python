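"""End-to-end pipeline: bundle processing, similarity scoring, statistics.

Two entry paths converge on the same analysis battery:

* :func:`process_bundle` reads an on-disk study bundle (raw 2000 Hz traces,
  MVC blocks, event annotations) and runs the full envelope / segmentation /
  time-normalization chain, producing trainee and model curves plus the
  amplitude and behavior tables;
* :func:`study_tables` takes an in-memory :class:`SimulatedStudy` (envelope
  fidelity) and assembles the same tables directly.

:func:`analyze_tables` then runs the statistical battery and
:func:`format_report` renders it as markdown mirroring the structure of a
results section (balance, learning, rmANOVA, paired contrasts, regressions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import emg_processing as emg
from . import similarity as sim
from . import stats as st
from .behavior import TrialLog
from .similarity import FULL_TRIAL, PHASES, _r2_last_axis
from .synthetic_data import SimulatedStudy

BASELINE_COVARIATES = ("age", "chop_frequency", "chop_ability",
                       "nhpt_right", "nhpt_left")


@dataclass
class StudyTables:
    """The tidy tables every analysis consumes."""

    manifest: pd.DataFrame          # subject, group, covariates, excluded
    curves: pd.DataFrame            # subject, group, session, muscle, scope, values
    model_curves: dict              # (muscle, scope) -> curve
    amplitude: pd.DataFrame         # subject, group, session, muscle, amplitude
    behavior: pd.DataFrame          # subject, group, session, ga, fl, md, ...
    excluded: set = field(default_factory=set)

    def drop_excluded(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.excluded or "muscle" not in df.columns:
            return df
        mask = [
            (s, m) not in self.excluded
            for s, m in zip(df["subject"], df["muscle"])
        ]
        return df[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# in-memory (envelope fidelity) path
# ---------------------------------------------------------------------------

def study_tables(study: SimulatedStudy) -> StudyTables:
    """Assemble analysis tables from a simulated (envelope-level) study."""
    cfg = study.config
    rows = []
    for j, (sid, grp) in enumerate(zip(study.manifest["subject"],
                                       study.manifest["group"])):
        for s in range(cfg.n_sessions):
            for mi, muscle in enumerate(cfg.muscles):
                phase_curves = study.phase_curves[j, s, mi]
                for pi, phase in enumerate(PHASES):
                    rows.append({"subject": sid, "group": grp, "session": s + 1,
                                 "muscle": muscle, "scope": phase,
                                 "values": phase_curves[pi]})
                rows.append({"subject": sid, "group": grp, "session": s + 1,
                             "muscle": muscle, "scope": FULL_TRIAL,
                             "values": np.concatenate(phase_curves)})
    return StudyTables(
        manifest=study.manifest,
        curves=pd.DataFrame(rows),
        model_curves=study.templates.as_model_curves(),
        amplitude=study.amplitude,
        behavior=study.behavior,
        excluded=set(study.excluded),
    )


def similarity_table(study: SimulatedStudy) -> pd.DataFrame:
    """Vectorized LFM scoring of a simulated study (exclusions dropped).

    Equivalent to :func:`emglfm.similarity.score_study` on the long curve
    table, but scores whole (subject, session) blocks per muscle at once.
    """
    cfg = study.config
    curves = study.phase_curves  # (n_subj, n_sess, n_mus, 3, 100)
    recs = []
    for mi, muscle in enumerate(cfg.muscles):
        per_scope = {}
        for pi, phase in enumerate(PHASES):
            per_scope[phase] = _r2_last_axis(
                curves[:, :, mi, pi, :], study.templates.curve(muscle, phase))
        full = curves[:, :, mi].reshape(curves.shape[0], curves.shape[1], -1)
        per_scope[FULL_TRIAL] = _r2_last_axis(full, study.templates.full_trial(muscle))
        for j, (sid, grp) in enumerate(zip(study.manifest["subject"],
                                           study.manifest["group"])):
            if (sid, muscle) in study.excluded:
                continue
            for s in range(cfg.n_sessions):
                for scope, r2 in per_scope.items():
                    recs.append({"subject": sid, "group": grp, "session": s + 1,
                                 "muscle": muscle, "scope": scope,
                                 "r_squared": float(r2[j, s])})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# on-disk (raw-trace) path
# ---------------------------------------------------------------------------

def _read_trace(path: Path, subject: str, session: int, muscle: str,
                sampling_rate: float) -> emg.EmgTrace:
    try:
        df = pd.read_csv(path)
        samples = df["amplitude"].to_numpy(float)
    except Exception as exc:
        raise ValueError(f"corrupted trace file {path}: {exc}") from exc
    return emg.EmgTrace(subject, session, muscle, samples, sampling_rate)


def _session_curves_from_trace(trace: emg.EmgTrace, log: TrialLog,
                               aggregation: str = "mean") -> dict:
    """Per-phase session curves (marble-averaged) from one raw trace."""
    env = emg.compute_envelope(trace)
    annotation = log.annotation()
    annotation.validate_against(trace)
    segments = emg.segment_phases(env, trace.sampling_rate, annotation)
    out = {}
    for phase in PHASES:
        marble_curves = [emg.time_normalize(segs[phase]) for segs in segments]
        out[phase] = emg.session_curve(marble_curves, how=aggregation)
    return out, env


def process_bundle(bundle_dir, aggregation: str = "mean") -> StudyTables:
    """Run the full processing chain over an on-disk raw study bundle."""
    root = Path(bundle_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    fs = float(manifest["config"]["sampling_rate"])
    muscles = tuple(manifest["config"]["muscles"])
    n_sessions = int(manifest["config"]["n_sessions"])

    # the expert's curves, processed by the identical chain
    with open(root / "model" / "events.json") as fh:
        model_log = TrialLog.from_json_dict(json.load(fh))
    model_curves = {}
    for muscle in muscles:
        trace = _read_trace(root / "model" / "traces" / f"{muscle}.csv",
                            "MODEL", 0, muscle, fs)
        phase_curves, _ = _session_curves_from_trace(trace, model_log, aggregation)
        for phase, c in phase_curves.items():
            model_curves[(muscle, phase)] = c
        model_curves[(muscle, FULL_TRIAL)] = emg.concatenate_phases(
            *[phase_curves[p] for p in PHASES])

    curve_rows, amp_rows, logs = [], [], []
    excluded = set()
    man_rows = []
    for entry in manifest["subjects"]:
        sid, grp = entry["id"], entry["group"]
        man_rows.append({"subject": sid, "group": grp,
                         **{k: entry[k] for k in BASELINE_COVARIATES if k in entry}})
        for m in entry.get("excluded", []):
            excluded.add((sid, m))
        mvc = {}
        for muscle in muscles:
            mvc_trace = _read_trace(root / "mvc" / sid / f"{muscle}.csv",
                                    sid, 0, muscle, fs)
            mvc[muscle] = emg.compute_mvc(mvc_trace)
        for s in range(1, n_sessions + 1):
            with open(root / "events" / sid / f"S{s}.json") as fh:
                log = TrialLog.from_json_dict(json.load(fh))
            logs.append(log)
            for muscle in muscles:
                if (sid, muscle) in excluded:
                    continue
                trace = _read_trace(root / "traces" / sid / f"S{s}" / f"{muscle}.csv",
                                    sid, s, muscle, fs)
                phase_curves, env = _session_curves_from_trace(trace, log, aggregation)
                amp_rows.append({
                    "subject": sid, "group": grp, "session": s, "muscle": muscle,
                    "amplitude": emg.mean_contraction_amplitude(
                        env, fs, log.annotation(), mvc[muscle]),
                })
                for phase, c in phase_curves.items():
                    curve_rows.append({"subject": sid, "group": grp, "session": s,
                                       "muscle": muscle, "scope": phase, "values": c})
                curve_rows.append({
                    "subject": sid, "group": grp, "session": s, "muscle": muscle,
                    "scope": FULL_TRIAL,
                    "values": emg.concatenate_phases(*[phase_curves[p] for p in PHASES]),
                })
    return StudyTables(
        manifest=pd.DataFrame(man_rows),
        curves=pd.DataFrame(curve_rows),
        model_curves=model_curves,
        amplitude=pd.DataFrame(amp_rows),
        behavior=bhv.session_table(logs),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# analysis battery
# ---------------------------------------------------------------------------

def analyze_tables(
    tables: StudyTables,
    similarity_scores: pd.DataFrame | None = None,
    final_session: int | None = None,
    pooled: bool = True,
    sphericity_correction: str | None = None,
    fdr_q: float = 0.05,
) -> dict:
    """Run the complete statistical battery on a study's tables.

    Returns a nested dict (JSON-serializable except for the raw tables):
    balance tests, behavioral learning tests, per-muscle mixed ANOVAs on
    amplitude and full-trial similarity, within-group paired S1-vs-S6
    similarity tests, the three regression hypotheses (full-trial plus the
    9-cell phase × muscle H3 battery under FDR), and the 9-predictor
    multiple regression per group.
    """
    if similarity_scores is None:
        similarity_scores = sim.score_study(
            tables.drop_excluded(tables.curves), tables.model_curves)
        similarity_scores = tables.drop_excluded(similarity_scores)
    last = final_session or int(tables.behavior["session"].max())

    results: dict = {"n_subjects": int(tables.manifest.shape[0]),
                     "final_session": last}

    # 1. group balance: covariates + S1 behavioral scores
    baseline = tables.manifest.merge(
        tables.behavior[tables.behavior["session"] == 1]
        [["subject", "ga", "fl", "md"]], on="subject")
    variables = [v for v in BASELINE_COVARIATES if v in baseline.columns]
    variables += ["ga", "fl", "md"]
    results["balance"] = [r.as_dict() for r in
                          st.balance_tests(baseline, variables, pooled=pooled)]

    # 2. behavioral learning effects on baseline-corrected scores
    corrected = bhv.baseline_correct(tables.behavior)
    results["learning"] = [r.as_dict() for r in
                           st.learning_tests(corrected, final_session=last,
                                             pooled=pooled)]

    # 3. EMG S1 balance + mixed ANOVAs per muscle
    amp = tables.drop_excluded(tables.amplitude)
    simil = similarity_scores
    full = simil[simil["scope"] == FULL_TRIAL]
    results["emg_s1_balance"] = []
    for muscle, chunk in amp[amp["session"] == 1].groupby("muscle"):
        groups = {g: v["amplitude"] for g, v in chunk.groupby("group")}
        (ga_, a), (gb_, b) = sorted(groups.items())
        results["emg_s1_balance"].append(st.two_sample_t(
            a, b, label=f"s1_amplitude:{muscle}", pooled=pooled,
            muscle=muscle, measure="amplitude").as_dict())
    for muscle, chunk in full[full["session"] == 1].groupby("muscle"):
        groups = {g: v["r_squared"] for g, v in chunk.groupby("group")}
        (ga_, a), (gb_, b) = sorted(groups.items())
        results["emg_s1_balance"].append(st.two_sample_t(
            a, b, label=f"s1_similarity:{muscle}", pooled=pooled,
            muscle=muscle, measure="similarity").as_dict())

    results["anova_amplitude"] = {}
    results["anova_similarity"] = {}
    for muscle, chunk in amp.groupby("muscle"):
        tbl = st.mixed_anova(chunk, "amplitude", correction=sphericity_correction)
        results["anova_amplitude"][muscle] = tbl.to_dict(orient="records")
    for muscle, chunk in full.groupby("muscle"):
        tbl = st.mixed_anova(chunk, "r_squared", correction=sphericity_correction)
        results["anova_similarity"][muscle] = tbl.to_dict(orient="records")

    # 4. within-group paired S1-vs-S6 similarity
    results["paired_s1_s6"] = [
        r.as_dict() for r in st.paired_s1_s6_tests(full, first=1, last=last)]
    means = (full[full["session"].isin([1, last])]
             .groupby(["group", "muscle", "session"])["r_squared"].mean())
    results["similarity_means"] = {
        f"{g}:{m}:S{s}": float(v) for (g, m, s), v in means.items()}

    # 5. regressions
    deltas = bhv.delta_table(tables.behavior, first=1, last=last)
    sim_deltas = sim.similarity_delta(simil, first=1, last=last)
    reg = {}
    reg["H1"] = st.run_regressions(
        "H1", deltas, simil, sim_deltas, baseline_behavior=tables.behavior,
        scopes=(FULL_TRIAL,), q=fdr_q).to_dict(orient="records")
    reg["H2"] = st.run_regressions(
        "H2", deltas, simil, sim_deltas, scopes=(FULL_TRIAL,),
        q=fdr_q).to_dict(orient="records")
    reg["H3_full_trial"] = st.run_regressions(
        "H3", deltas, simil, sim_deltas, scopes=(FULL_TRIAL,),
        q=fdr_q).to_dict(orient="records")
    reg["H3_by_phase"] = st.run_regressions(
        "H3", deltas, simil, sim_deltas, scopes=PHASES,
        q=fdr_q).to_dict(orient="records")
    results["regressions"] = reg

    # 6. multiple regression ΔGA ~ 9 similarity gains, per group
    results["multiple_regression"] = {}
    for group, chunk in sim_deltas[sim_deltas["scope"] != FULL_TRIAL] \
            .groupby("group"):
        wide = chunk.pivot_table(index="subject", columns=["muscle", "scope"],
                                 values="delta_r_squared").dropna()
        wide.columns = [f"{m}_{p}" for m, p in wide.columns]
        resp = deltas[deltas["group"] == group].set_index("subject")["delta_ga"]
        common = wide.index.intersection(resp.index)
        try:
            results["multiple_regression"][group] = st.multiple_regression(
                wide.loc[common], resp.loc[common], label=f"multiple:{group}")
        except ValueError as exc:
            results["multiple_regression"][group] = {"error": str(exc)}
    return results


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt_t(d: dict) -> str:
    df = d["df"][0]
    df_s = f"{df:g}"
    s = f"t({df_s}) = {d['stat']:.2f}, p = {d['p']:.3g}"
    if "effect_size" in d:
        s += f", Cohen's d = {abs(d['effect_size']):.2f}"
    return s


def format_report(results: dict) -> str:
    """Human-readable markdown report of the full battery."""
    lines = ["# Training study results", ""]
    lines += ["## Group balance at baseline", ""]
    for d in results["balance"]:
        lines.append(f"- {d['context'].get('variable', d['label'])}: {_fmt_t(d)}")
    lines += ["", "## Behavioral learning (baseline-corrected final session)", ""]
    for d in results["learning"]:
        lines.append(f"- {d['label']}: {_fmt_t(d)}")
    lines += ["", "## EMG initial-score balance", ""]
    for d in results["emg_s1_balance"]:
        lines.append(f"- {d['label']}: {_fmt_t(d)}")
    for key, title in (("anova_amplitude", "Mixed ANOVA — contraction amplitude"),
                       ("anova_similarity", "Mixed ANOVA — trainee-model similarity")):
        lines += ["", f"## {title}", ""]
        for muscle, rows in results[key].items():
            for r in rows:
                if not np.isfinite(r.get("F", np.nan)):
                    continue
                lines.append(
                    f"- {muscle} {r['effect']}: F({r['df1']:g},{r['df2']:g}) ="
                    f" {r['F']:.2f}, p = {r['p']:.3g}")
    lines += ["", "## Paired S1 vs S6 similarity (within group)", ""]
    for d in results["paired_s1_s6"]:
        lines.append(f"- {d['label']}: {_fmt_t(d)}")
    lines += ["", "## Regressions (standardized β; BH-FDR within group)", ""]
    for hyp, rows in results["regressions"].items():
        lines.append(f"### {hyp}")
        for r in rows:
            flag = " *" if r.get("significant_fdr") else ""
            lines.append(
                f"- {r['group']} {r['muscle']} {r['scope']}: β = {r['beta']:.2f},"
                f" R² = {r['r_squared']:.2f}, p = {r['p']:.3g}"
                f" (p_FDR = {r['p_fdr']:.3g}){flag}")
        lines.append("")
    lines += ["## Multiple regression (ΔGA ~ 9 similarity gains)", ""]
    for group, d in results["multiple_regression"].items():
        if "error" in d:
            lines.append(f"- {group}: {d['error']}")
        else:
            lines.append(
                f"- {group}: R = {d['multiple_r']:.2f},"
                f" F({d['df'][0]},{d['df'][1]}) = {d['F']:.2f}, p = {d['p']:.3g}")
    return "\n".join(lines) + "\n"


def write_results(results: dict, out_dir, report: bool = True) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=float)
    if report:
        (out / "report.md").write_text(format_report(results))
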