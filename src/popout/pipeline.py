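"""End-to-end orchestration: simulate -> preprocess -> decode -> spectra -> stats.

`run_pipeline` executes the whole synthetic study for a configured number of
participants and returns a ResultsBundle of tidy tables plus group-level
cluster statistics; `summarize_conditions` reduces the bundle to condition
cell means with paired differences and descriptive nonparametric tests (the
original mixed-model inference is intentionally left to external stats
environments — the exported tables carry everything those models need).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import spectral
from .cluster import build_neighbors, cluster_permutation, cluster_permutation_1d
from .decoding import (DEFAULT_LAMBDA_GRID, reconstruct_envelope,
                       score_reconstruction, train_decoder)
from .exceptions import ConfigurationError
from .preprocessing import prepare_for_decoding, rereference
from .pupil import epoch_and_baseline, preprocess_trace
from .synthetic import (PRIORS, STIMULUS_TYPES, ConditionEffects, NoiseParams,
                        SessionConfig, build_stimulus_pool, simulate_session)
from .utils import resample_to

log = logging.getLogger("popout")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run; defaults echo the study design."""
    n_participants: int = 19
    n_pairs: int = 80
    n_trials: int | None = None         # balanced subset per participant
    seed: int = 0
    training_duration: float = 120.0
    epoch_span: tuple[float, float] = (-5.0, 15.0)
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_folds: int = 8
    n_perm: int = 1000
    bands: tuple = ("delta", "theta", "alpha", "beta")
    effects: ConditionEffects = field(default_factory=ConditionEffects.paper_like)
    noise: NoiseParams = field(default_factory=NoiseParams)
    simulate_pupil: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("need at least one participant")
        if self.n_pairs % 5:
            raise ConfigurationError("n_pairs must be divisible by 5")
        for f, v in asdict(self).items():
            log.info("config %s = %r", f, v)

    def config_hash(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return sorted((str(k), _clean(v)) for k, v in obj.items())
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj
        blob = json.dumps(_clean(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def smoke(cls, seed: int = 0) -> "RunConfig":
        """Small configuration for quick end-to-end checks."""
        return cls(n_participants=3, n_trials=12, n_perm=100,
                   training_duration=60.0, seed=seed,
                   lambda_grid=(1e2,), epoch_span=(-2.5, 13.0))


@dataclass
class ResultsBundle:
    scores: pd.DataFrame                 # reconstruction scores
    band_power: pd.DataFrame             # per participant/trial/channel/band
    pupil_epochs: pd.DataFrame           # per participant/trial dilation curves
    cluster_results: dict                # contrast -> ClusterResult
    config_hash: str = ""
    seed: int = 0


def _session_tables(session, cfg: RunConfig, bands) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-participant reconstruction, band-power, and pupil tables."""
    env_tr = session.training_envelope
    eeg_tr = session.training_eeg
    from .preprocessing import EEGEpoch
    tr_epoch = EEGEpoch(data=eeg_tr, fs=500.0, t0=0.0,
                        channels=session.layout.names)
    dur_tr = eeg_tr.shape[1] / 500.0
    prepared_tr = prepare_for_decoding(tr_epoch, dur_tr)
    model = train_decoder(prepared_tr, env_tr, lambda_grid=cfg.lambda_grid,
                          n_folds=cfg.n_folds)

    score_rows, power_rows, pupil_rows = [], [], []
    for trial in session.design:
        env = session.trial_envelopes[trial.sentence_id]
        dur = len(env.samples) / env.fs
        for pres in (1, 2):
            epoch = session.trial_epochs[(trial.trial_index, pres)]
            prepared = prepare_for_decoding(epoch, dur)
            est = reconstruct_envelope(model, prepared)
            for sc in score_reconstruction(est, env, trial_index=trial.trial_index,
                                           presentation=pres):
                score_rows.append({
                    "participant": session.participant_index,
                    "trial": trial.trial_index, "presentation": pres,
                    "iteration": sc.iteration, "r": sc.r,
                    "stimulus_type": trial.stimulus_type, "prior": trial.prior})
            mast = rereference(epoch, "linked_mastoids")
            tfr = spectral.tf_decompose(mast, tmin=0.0, tmax=3.4)
            for band in bands:
                tab = spectral.band_average(tfr, spectral.BANDS[band],
                                            channels=epoch.channels)
                tab["participant"] = session.participant_index
                tab["trial"] = trial.trial_index
                tab["presentation"] = pres
                tab["band"] = band
                tab["stimulus_type"] = trial.stimulus_type
                tab["prior"] = trial.prior
                power_rows.append(tab)
        if trial.trial_index in session.pupil:
            trace = session.pupil[trial.trial_index]
            averaged, dropouts = preprocess_trace(trace)
            if averaged is None:
                continue
            e1, e2 = epoch_and_baseline(averaged, trace.fs, trace.onset_1,
                                        trace.onset_2,
                                        trial_index=trial.trial_index)
            curve = resample_to(e2.samples, trace.fs, 10.0)
            for i, v in enumerate(curve):
                pupil_rows.append({
                    "participant": session.participant_index,
                    "trial": trial.trial_index, "time": -1.0 + i / 10.0,
                    "dilation": v, "stimulus_type": trial.stimulus_type,
                    "prior": trial.prior})
    scores = pd.DataFrame(score_rows)
    power = (pd.concat(power_rows, ignore_index=True)
             if power_rows else pd.DataFrame())
    pupil = pd.DataFrame(pupil_rows)
    return scores, power, pupil


def _powers_by_condition(power: pd.DataFrame, band: str):
    """participant x channel x 1 arrays of presentation-2 band power per prior."""
    sel = power[(power["band"] == band) & (power["presentation"] == 2)]
    out = {}
    for prior in PRIORS:
        sub = sel[sel["prior"] == prior]
        pivot = sub.groupby(["participant", "channel"], sort=True)[
            "log10_power"].mean().unstack()
        out[prior] = pivot.to_numpy()[:, :, None]
    return out


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute all stages and assemble the bundle; deterministic per (config, seed)."""
    t_start = time.time()
    cfg = config
    pool = build_stimulus_pool(cfg.n_pairs, cfg.seed)
    sess_cfg = SessionConfig(n_pairs=cfg.n_pairs,
                             training_duration=cfg.training_duration,
                             epoch_span=cfg.epoch_span, n_trials=cfg.n_trials,
                             noise=cfg.noise,
                             simulate_pupil_traces=cfg.simulate_pupil)
    all_scores, all_power, all_pupil = [], [], []
    for p in range(cfg.n_participants):
        log.info("participant %d/%d", p + 1, cfg.n_participants)
        session = simulate_session(pool, p, cfg.effects, cfg.seed, sess_cfg)
        s, pw, pu = _session_tables(session, cfg, cfg.bands)
        all_scores.append(s)
        all_power.append(pw)
        all_pupil.append(pu)
    scores = pd.concat(all_scores, ignore_index=True)
    power = pd.concat(all_power, ignore_index=True)
    pupil = pd.concat(all_pupil, ignore_index=True)

    from .layout import ChannelLayout
    graph = build_neighbors(ChannelLayout.load_default())
    cluster_results = {}
    for band in ("theta", "alpha"):
        if band not in cfg.bands:
            continue
        arrays = _powers_by_condition(power, band)
        for prior in ("P+", "P-"):
            a, b = arrays[prior], arrays["P0"]
            if len(a) and a.shape == b.shape:
                cluster_results[f"{band}:{prior}-P0"] = cluster_permutation(
                    a, b, graph, n_perm=cfg.n_perm, seed=cfg.seed)
    if len(pupil):
        piv = pupil.groupby(["participant", "prior", "time"])["dilation"].mean()
        for prior in ("P+", "P-"):
            try:
                a = piv.xs(prior, level="prior").unstack().to_numpy()
                b = piv.xs("P0", level="prior").unstack().to_numpy()
                cluster_results[f"pupil:{prior}-P0"] = cluster_permutation_1d(
                    a, b, n_perm=cfg.n_perm, seed=cfg.seed)
            except KeyError:
                pass

    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return ResultsBundle(scores=scores, band_power=power, pupil_epochs=pupil,
                         cluster_results=cluster_results,
                         config_hash=cfg.config_hash(), seed=cfg.seed)


def summarize_conditions(bundle: ResultsBundle) -> pd.DataFrame:
    """Cell means per participant/stimulus type/prior, paired diffs vs P0,
    and descriptive Wilcoxon p-values (not mixed-model inference)."""
    rows = []
    sc = bundle.scores
    it1 = sc[(sc["iteration"] == 1) & (sc["presentation"] == 2)]
    cell = it1.groupby(["participant", "stimulus_type", "prior"])["r"].mean()
    for (stim,), _ in [((s,), None) for s in STIMULUS_TYPES]:
        for prior in PRIORS:
            try:
                vals = cell.xs((stim, prior), level=("stimulus_type", "prior"))
            except KeyError:
                continue
            row = {"measure": "reconstruction_r", "stimulus_type": stim,
                   "prior": prior, "mean": vals.mean(), "sem": vals.sem()}
            if prior != "P0":
                try:
                    p0 = cell.xs((stim, "P0"), level=("stimulus_type", "prior"))
                    common = vals.index.intersection(p0.index)
                    d = vals.loc[common] - p0.loc[common]
                    row["diff_vs_P0"] = d.mean()
                    if len(d) >= 2 and d.abs().sum() > 0:
                        row["wilcoxon_p"] = float(
                            sstats.wilcoxon(d).pvalue)
                except KeyError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)
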