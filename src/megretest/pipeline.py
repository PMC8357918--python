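"""End-to-end orchestration: simulate -> beamform -> epoch -> spectra +
connectivity -> consistency statistics, with per-stage provenance.

Per-timepoint processing order mirrors the two hardware pipelines:

* BL   — sensors already at 312.5 Hz: beamform, then epoch.
* FU1  — sensors at 625 Hz: decimate sensors 2x to 312.5 Hz, beamform, epoch.
* FU2  — sensors at 1250 Hz: beamform at the native rate, decimate the
         reconstructed source series 4x, then epoch.

Everything is deterministic given the master seed; per-subject/session random
streams are derived by fixed hashing of (seed, subject, timepoint).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .beamformer import reconstruct_roi_series
from .cohort import (CohortSpec, SensorRecording, make_cohort, simulate_session,
                     TARGET_RATE)
from .connectivity import ALPHA, BETA, aec_matrix
from .forward import (HeadModel, build_sensor_array, lead_field_block,
                      source_layout)
from .preprocess import (decimate, flag_bad_channels, reject_artifact_epochs,
                         split_epochs, EpochSet)
from .spectral import SPECTRAL_BAND, average_normalized_spectrum, peak_frequency
from .stats import (build_consistency_table, compare_within_between, paired_t,
                    rm_anova, roiwise_consistency_map, StatResult,
                    WITHIN_PAIRS)

__version__ = "0.1.0"

BAND_DEFS = {"alpha": ALPHA, "beta": BETA}


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    bands: dict = field(default_factory=lambda: dict(BAND_DEFS))
    spectral_band: tuple[float, float] = SPECTRAL_BAND
    beamformer_band: tuple[float, float] = (0.5, 48.0)
    bad_channel_z: float = 4.0
    artifact_mad: float = 6.0
    covariance_reg: float = 0.05
    outdir: str | None = None
    seed: int | None = None  # overrides cohort.seed when set

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.cohort.seed = int(self.seed)
        nyq = TARGET_RATE / 2.0
        for name, (lo, hi) in {**self.bands,
                               "spectral": self.spectral_band}.items():
            if not (0.0 < lo < hi <= nyq):
                raise ConfigError(f"band {name}={lo}-{hi} outside (0, {nyq})")
        lo, hi = self.beamformer_band
        if not (0.0 < lo < hi):
            raise ConfigError("invalid beamformer band")


class _ForwardCache:
    """Sensor arrays and ROI lead fields are geometry-only; reuse them across
    sessions and cohorts."""

    def __init__(self) -> None:
        self._gain: dict = {}
        self._blocks: dict = {}

    def layout(self, head_radius: float):
        key = ("layout", head_radius)
        if key not in self._gain:
            self._gain[key] = source_layout(head_radius=head_radius)
        return self._gain[key]

    def lead_blocks(self, system: str, head_radius: float) -> np.ndarray:
        key = (system, head_radius)
        if key not in self._blocks:
            positions, _, _ = self.layout(head_radius)
            array = build_sensor_array(system)
            head = HeadModel(sphere_radius=head_radius)
            self._blocks[key] = np.stack(
                [lead_field_block(array, head, p) for p in positions])
        return self._blocks[key]


_CACHE = _ForwardCache()


def process_session(rec: SensorRecording, centroids: np.ndarray,
                    config: RunConfig, lead_blocks: np.ndarray | None = None
                    ) -> tuple[EpochSet, dict]:
    """Sensor recording -> clean 312.5 Hz source EpochSet + provenance dict."""
    bad = flag_bad_channels(rec, z_thresh=config.bad_channel_z)
    rec.good_channel_mask = ~bad
    data, rate = rec.data, rec.rate
    if rate > TARGET_RATE and rec.system != "vectorview306":
        data, rate = decimate(data, rate)
        rec = SensorRecording(data=data, rate=rate, array=rec.array,
                              head=rec.head, system=rec.system,
                              good_channel_mask=rec.good_channel_mask)
    series, weights = _reconstruct(rec, centroids, config, lead_blocks)
    if rec.rate > TARGET_RATE:
        series, _ = decimate(series, rec.rate)
    epochs = split_epochs(series, TARGET_RATE)
    n_before = epochs.n_epochs
    epochs = reject_artifact_epochs(epochs, amp_thresh_mad=config.artifact_mad)
    prov = dict(system=rec.system, native_rate=rec.rate,
                n_bad_channels=int(bad.sum()),
                bad_channels=np.where(bad)[0].tolist(),
                n_epochs_before=n_before, n_epochs=epochs.n_epochs,
                kept_epoch_ids=epochs.kept_epoch_ids.tolist())
    return epochs, prov


def _reconstruct(rec, centroids, config, lead_blocks):
    if lead_blocks is None:
        return reconstruct_roi_series(rec, centroids,
                                      band=config.beamformer_band,
                                      reg=config.covariance_reg)
    # cached lead fields: reimplement the per-ROI loop with precomputed blocks
    from .beamformer import (estimate_covariance, optimal_orientation,
                             compute_weights, BeamformerWeights)
    from .connectivity import brickwall_bandpass
    good = rec.good_channel_mask
    filtered = brickwall_bandpass(rec.data[good], config.beamformer_band,
                                  rec.rate)
    cov = estimate_covariance(filtered, rec.rate,
                              band=config.beamformer_band,
                              reg=config.covariance_reg, prefiltered=True)
    c_inv = np.linalg.inv(cov.c)
    n = len(centroids)
    w_rows = np.empty((n, filtered.shape[0]))
    orientations = np.empty((n, 3))
    for i in range(n):
        l_block = lead_blocks[i][good]
        nu = optimal_orientation(l_block, cov.c, c_inv=c_inv)
        w_rows[i] = compute_weights(l_block, cov.c, nu, c_inv=c_inv)
        orientations[i] = nu
    return w_rows @ filtered, BeamformerWeights(w_rows, orientations, True)


def run_cohort_sessions(config: RunConfig) -> tuple[dict, dict]:
    """Simulate and process every subject/timepoint.

    Returns (sessions, provenance): sessions maps (subject, timepoint) to
    {"epochs", "spectrum", "peak_hz", "conn"}.
    """
    spec = config.cohort
    fingerprints = make_cohort(spec)
    positions, orientations, labels = _CACHE.layout(spec.head_radius)
    sessions, prov = {}, {}
    for si, fp in enumerate(fingerprints):
        for tp in spec.timepoints:
            t0 = time.perf_counter()
            try:
                rec, _src = simulate_session(fp, spec, tp, si,
                                             positions, orientations)
                blocks = _CACHE.lead_blocks(rec.system, spec.head_radius)
                epochs, p = process_session(rec, positions, config, blocks)
                spectrum = average_normalized_spectrum(
                    epochs, band=config.spectral_band)
                conn = {name: aec_matrix(epochs, band)
                        for name, band in config.bands.items()}
            except Exception as exc:
                raise DataError(
                    f"stage failure in session subject={fp.subject} "
                    f"timepoint={tp}: {exc}") from exc
            p["runtime_s"] = round(time.perf_counter() - t0, 3)
            p["peak_hz"] = peak_frequency(spectrum)
            sessions[(fp.subject, tp)] = dict(
                epochs=epochs, spectrum=spectrum, peak_hz=p["peak_hz"],
                conn=conn)
            prov[f"{fp.subject}/{tp}"] = p
    return sessions, prov


def consistency_statistics(table: pd.DataFrame,
                           timepoints=("BL", "FU1", "FU2")) -> dict:
    """Table 1-style statistics: per-metric RM-ANOVA of within values (over
    the three pairs) and between values (over timepoints), the within-vs-
    between unpaired t-test, and post-hoc paired t-tests between pairs."""
    out = {}
    pair_keys = [f"{a}-{b}" for a, b in WITHIN_PAIRS]
    for metric in sorted(table.metric.unique()):
        sub = table[table.metric == metric]
        within = sub[sub.kind == "within"].pivot(index="subject",
                                                columns="key", values="value")
        between = sub[sub.kind == "between"].pivot(index="subject",
                                                   columns="key",
                                                   values="value")
        within = within[pair_keys]
        between = between[list(timepoints)]
        res = dict(
            rm_anova_within=rm_anova(within.to_numpy()),
            rm_anova_between=rm_anova(between.to_numpy()),
            within_vs_between=compare_within_between(table, metric),
        )
        posthoc = {}
        for i, ka in enumerate(pair_keys):
            for kb in pair_keys[i + 1:]:
                posthoc[f"{ka} vs {kb}"] = paired_t(
                    within[ka].to_numpy(), within[kb].to_numpy(),
                    name=f"paired[{metric}] {ka} vs {kb}")
        res["posthoc_within"] = posthoc
        out[metric] = res
    return out


def roiwise_group_maps(sessions: dict, bands: dict,
                       subjects: list[str]) -> dict:
    """Per band, the mean ROI-wise within-subject consistency map over all
    subjects and the three timepoint pairs (displayable on a template brain)."""
    maps = {}
    for bname in bands:
        acc = []
        for s in subjects:
            for t1, t2 in WITHIN_PAIRS:
                acc.append(roiwise_consistency_map(
                    sessions[(s, t1)]["conn"][bname],
                    sessions[(s, t2)]["conn"][bname]))
        maps[bname] = np.mean(acc, axis=0)
    return maps


def _stat_to_dict(s: StatResult) -> dict:
    d = dict(name=s.name, statistic=s.statistic, df=s.df, p=s.p)
    if s.effect_size is not None:
        d["partial_eta_squared"] = s.effect_size
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Full run; returns the run report and, if ``config.outdir`` is set,
    writes spectra, connectivity matrices, the consistency table and the JSON
    report with a checksummed file manifest."""
    sessions, prov = run_cohort_sessions(config)
    table = build_consistency_table(
        {k: dict(spectrum=v["spectrum"], conn=v["conn"])
         for k, v in sessions.items()},
        timepoints=config.cohort.timepoints, bands=tuple(config.bands))
    stats = consistency_statistics(table, timepoints=config.cohort.timepoints)
    subjects = sorted({s for s, _ in sessions})
    roi_maps = roiwise_group_maps(sessions, config.bands, subjects)
    report = dict(
        roiwise_within_consistency={k: v.tolist()
                                    for k, v in roi_maps.items()},
        version=__version__,
        seed=config.cohort.seed,
        parameters=dict(
            n_subjects=config.cohort.n_subjects,
            duration_s=config.cohort.duration_s,
            bands=config.bands, spectral_band=config.spectral_band,
            beamformer_band=config.beamformer_band,
            bad_channel_z=config.bad_channel_z,
            artifact_mad=config.artifact_mad,
            covariance_reg=config.covariance_reg,
            noise=config.cohort.noise),
        sessions=prov,
        statistics={m: {k: (_stat_to_dict(v) if isinstance(v, StatResult)
                            else {kk: _stat_to_dict(vv)
                                  for kk, vv in v.items()})
                        for k, v in res.items()}
                    for m, res in stats.items()},
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _, _, roi_labels = _CACHE.layout(config.cohort.head_radius)
        manifest = {}
        for (subj, tp), sess in sessions.items():
            mio.write_spectrum(outdir / f"spectrum_{subj}_{tp}.tsv",
                               sess["spectrum"])
            manifest[f"spectrum_{subj}_{tp}.tsv"] = mio.sha256_of(
                outdir / f"spectrum_{subj}_{tp}.tsv")
            for bname, mat in sess["conn"].items():
                fn = f"aec_{bname}_{subj}_{tp}.tsv"
                mio.write_matrix(outdir / fn, mat, roi_labels)
                manifest[fn] = mio.sha256_of(outdir / fn)
        mio.write_table(outdir / "consistency_table.tsv", table)
        manifest["consistency_table.tsv"] = mio.sha256_of(
            outdir / "consistency_table.tsv")
        report["manifest"] = manifest
        mio.write_report(outdir / "report.json", report)
    report["consistency_table"] = table
    return report
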