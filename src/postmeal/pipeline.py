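"""End-to-end orchestration: simulate -> featurize -> characterize ->
predict -> path model -> MR -> network MR, with a run manifest.

Each enabled stage writes its outputs under the run directory and adds
an entry (parameters, seeds, output hashes) to ``manifest.json``; a rerun
with the same configuration reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import characterize as ch
from . import io as pio
from . import mr as mrmod
from . import network, pathmodel, predict, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "features", "characterize", "predict", "pathmodel", "mr", "network_mr")


@dataclass
class PipelineConfig:
    out_dir: str | Path = "postmeal_run"
    seed: int = 0
    n_participants: int = 200
    stages: tuple[str, ...] = ALL_STAGES
    mr_config: synthetic.MRSimConfig | None = None
    network_config: synthetic.NetworkMRSimConfig | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    dataset = None
    features = None

    def record(stage: str, params: dict, paths: list[Path]):
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {p.name: _hash_file(p) for p in paths},
        }

    if "simulate" in config.stages:
        cfg = synthetic.CohortSimConfig(n_participants=config.n_participants, seed=config.seed)
        dataset = synthetic.simulate_cohort(cfg)
        paths = [
            pio.write_curves(dataset.curves, out / "curves.tsv"),
            pio.write_markers(dataset.markers, out / "markers.tsv"),
            pio.write_covariates(dataset.covariates, out / "covariates.tsv"),
            pio.write_truth(dataset.truth, out / "truth.json"),
        ]
        record("simulate", {"n": config.n_participants, "seed": config.seed}, paths)

    if "features" in config.stages:
        if dataset is None:
            raise RuntimeError("features stage requires the simulate stage")
        features = pio.feature_table(dataset.curves)
        paths = [pio.write_table(features.reset_index(), out / "features.tsv")]
        record("features", {}, paths)

    if "characterize" in config.stages:
        report = {}
        for marker in ("il6", "glyca"):
            wide = dataset.marker_wide(marker)
            rs = ch.responder_summary(wide["value_0h"], wide["value_6h"])
            report[marker] = {
                "fraction_rising": rs.fraction_rising,
                "pct_rise": rs.pct_rise,
                "responder_pct_rise": rs.responder_pct_rise,
                "cv_fasting": ch.cross_sectional_cv(wide["value_0h"]).cv_pct,
                "cv_6h": ch.cross_sectional_cv(wide["value_6h"]).cv_pct,
                "levene_p": ch.levene_test(
                    wide["value_0h"], wide["value_4h"], wide["value_6h"]
                ).p_value,
            }
        path = out / "characterization.json"
        path.write_text(json.dumps(report, indent=2) + "\n")
        record("characterize", {}, [path])

    if "predict" in config.stages:
        glyca6 = dataset.marker_wide("glyca")["value_6h"]
        drop = [c for c in features.columns if c.endswith("tmax") or "tmax" in c]
        x = features.drop(columns=drop).loc[glyca6.index]
        rf = predict.rf_rank(x, glyca6, seed=config.seed)
        fit = predict.multivariable_fit(glyca6, x[["tg_max", "glu_max1"]])
        labels, cutoff = predict.dichotomize_at_percentile(glyca6.to_numpy(), 70.0)
        roc = predict.roc_auc(x["tg_max"].to_numpy(), labels, "tg_max")
        path = out / "prediction.json"
        path.write_text(
            json.dumps(
                {
                    "rf_ranking": rf.features,
                    "rf_importances": list(map(float, rf.importances)),
                    "r2": rf.r2,
                    "q2": rf.q2,
                    "ols_r2": fit.r2,
                    "roc_auc_tg_max": roc.auc,
                    "glyca_cutoff": cutoff,
                },
                indent=2,
            )
            + "\n"
        )
        record("predict", {"seed": config.seed}, [path])

    if "pathmodel" in config.stages:
        wide = dataset.marker_wide("glyca")
        data = dataset.covariates.set_index("participant_id").join(wide)
        data["glyca_fasting"] = data["value_0h"]
        data["glyca_6h"] = data["value_6h"]
        spec = pathmodel.PathSpec(
            nodes=("vfm", "tg_fasting", "glyca_fasting", "glyca_6h"),
            edges=(
                ("vfm", "tg_fasting"),
                ("tg_fasting", "glyca_fasting"),
                ("vfm", "glyca_fasting"),
                ("glyca_fasting", "glyca_6h"),
                ("tg_fasting", "glyca_6h"),
            ),
        )
        fit = pathmodel.fit_path_model(data, spec)
        path = out / "pathmodel.json"
        path.write_text(
            json.dumps(
                {
                    "chi2": fit.chi2,
                    "df": fit.df,
                    "cfi": fit.cfi,
                    "tli": fit.tli,
                    "rmsea": fit.rmsea,
                    "edges": fit.estimates.to_dict(orient="records"),
                },
                indent=2,
            )
            + "\n"
        )
        record("pathmodel", {}, [path])

    if "mr" in config.stages:
        cfg = config.mr_config or synthetic.MRSimConfig(seed=config.seed)
        exp, outc = synthetic.simulate_two_sample_gwas(cfg)
        pio.write_summary_stats(exp, out / "exposure_stats.tsv")
        pio.write_summary_stats(outc, out / "outcome_stats.tsv")
        hs = mrmod.harmonize(exp, outc)
        est = mrmod.ivw(hs, model="random")
        egger = mrmod.mr_egger(hs)
        raps = mrmod.mr_raps(hs)
        presso = mrmod.mr_presso(hs, seed=config.seed)
        q = mrmod.cochran_q(hs, mrmod.ivw(hs))
        f_panel = mrmod.instrument_strength(exp)
        path = out / "mr.json"
        path.write_text(
            json.dumps(
                {
                    "ivw_beta": est.beta,
                    "ivw_se": est.se,
                    "ivw_p": est.p,
                    "egger_beta": egger.slope.beta,
                    "egger_intercept": egger.intercept,
                    "egger_intercept_p": egger.intercept_p,
                    "raps_beta": raps.beta,
                    "presso_global_p": presso.global_p,
                    "presso_outliers": presso.outliers,
                    "q": q.statistic,
                    "q_p": q.p,
                    "mean_f": f_panel.mean_f,
                },
                indent=2,
            )
            + "\n"
        )
        record("mr", {"seed": cfg.seed}, [path, out / "exposure_stats.tsv", out / "outcome_stats.tsv"])

    if "network_mr" in config.stages:
        cfg = config.network_config or synthetic.NetworkMRSimConfig(seed=config.seed)
        tables = synthetic.simulate_network_gwas(cfg)
        report = network.run_network_mr(
            tables["exposure"], tables["mediator"], tables["outcome"],
            tables["exposure_instruments"], tables["mediator_instruments"],
        )
        med = report.mediation
        path = out / "network_mr.json"
        path.write_text(
            json.dumps(
                {
                    "alpha": med.alpha,
                    "beta": med.beta_med,
                    "gamma": med.gamma_total,
                    "indirect": med.indirect,
                    "proportion": med.proportion,
                    "proportion_pct": med.proportion_pct,
                    "reverse_beta": report.reverse.beta,
                    "reverse_p": report.reverse.p,
                },
                indent=2,
            )
            + "\n"
        )
        record("network_mr", {"seed": cfg.seed}, [path])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
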