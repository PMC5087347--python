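"""End-to-end pipeline: config, artifact writers, and the run driver.

A run goes simulate/load → band-power features → z-score → trial split →
rank (ReliefF or F-score) → select (top-N features / MRCS / X-MRCS) →
validate, writing each artifact as delimited text with the config hash and
seed embedded so every output is traceable to the exact configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptive import ClassifierSpec, xmrcs
from .evaluation import validate_selection
from .features import (
    FeatureTable,
    extract_features,
    split_dataset,
    zscore,
)
from .montage import lobe_of
from .selection import ChannelWeights, channels_from_top_features, mrcs
from .synthetic import GeneratorSpec, generate_subject, load_trialset
from .weighting import ReliefFConfig, fscore, relieff

log = logging.getLogger("eegselect")


@dataclass
class RunConfig:
    """All knobs of one end-to-end run, with the standard protocol defaults:

    4-s non-overlapping windows, the four canonical bands, ReliefF k = 10,
    X-MRCS epsilon = 0.01 with at most 50 iterations, five stratified
    10-fold cross-validations.
    """

    input_path: str | None = None  # None → simulate
    window_seconds: float = 4.0
    overlap: float = 0.0
    bands: dict | None = None  # band name → [low Hz, high Hz]; None → canonical four
    relieff_k: int = 10
    method: str = "relieff"  # relieff | fscore
    strategy: str = "mrcs"  # topn-features | mrcs | xmrcs
    top_n_features: int = 32
    epsilon: float = 0.01
    max_iterations: int = 50
    cv_folds: int = 10
    cv_repeats: int = 5
    seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorSpec overrides

    def __post_init__(self) -> None:
        effects = self.generator.get("effect_map")
        if effects:
            # serializable form: "class/channel/band" → multiplier
            self.generator = dict(self.generator)
            self.generator["effect_map"] = {
                (k if isinstance(k, str) else "/".join(str(p) for p in k)): float(v)
                for k, v in effects.items()
            }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(config: RunConfig) -> str:
    return f"# config_hash: {config.config_hash()}\n# seed: {config.seed}\n"


def write_table(path: Path, frame: pd.DataFrame, config: RunConfig) -> None:
    """Write a delimited-text artifact with the config hash and seed embedded."""
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_feature_table(path) -> FeatureTable:
    """Rebuild a FeatureTable from its tabular-text artifact.

    Columns are ``trial``, ``label`` and one ``<channel>_<band>`` column per
    feature; the feature map is reconstructed from the header names.
    """
    frame = read_table(path)
    feature_cols = [c for c in frame.columns if c not in ("trial", "label")]
    channels, bands = zip(*(c.rsplit("_", 1) for c in feature_cols))
    names = list(dict.fromkeys(channels))
    return FeatureTable(
        values=frame[feature_cols].to_numpy(float),
        labels=frame["label"].to_numpy(str),
        feature_channels=np.array([names.index(c) for c in channels]),
        feature_bands=np.array(bands),
        trial_of_sample=frame["trial"].to_numpy(int),
        channel_names=names,
        normalized=True,
        band_names=tuple(dict.fromkeys(bands)),
    )


def feature_table_frame(table: FeatureTable) -> pd.DataFrame:
    frame = pd.DataFrame(table.values, columns=table.feature_names)
    frame.insert(0, "label", table.labels)
    frame.insert(0, "trial", table.trial_of_sample)
    return frame


def weights_frame(names: list[str], weights: np.ndarray, ranking: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [names[i] for i in ranking],
            "weight": weights[ranking],
        }
    )


def channel_ranking_frame(cw: ChannelWeights) -> pd.DataFrame:
    names = cw.channel_names or [f"CH{i:02d}" for i in range(cw.n_channels)]
    return pd.DataFrame(
        {
            "rank": np.arange(1, cw.n_channels + 1),
            "channel": [names[i] for i in cw.ranking],
            "weight": cw.weights[cw.ranking],
            "lobe": [lobe_of(names[i]) for i in cw.ranking],
        }
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline, writing artifacts under *outdir*.

    Returns a dict of the in-memory results (tables, weights, curve, trace).
    Any stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.input_path is None:
            stage = "simulate"
            overrides = dict(config.generator)
            effects = {
                (cls, int(ch), band): mult
                for key, mult in (overrides.pop("effect_map", {}) or {}).items()
                for cls, ch, band in [key.split("/")]
            }
            spec = GeneratorSpec(seed=config.seed, effect_map=effects, **overrides)
            log.info("simulating subject: %d channels, %d trials", spec.n_channels, spec.n_trials)
            trials = generate_subject(spec)
        else:
            trials = load_trialset(config.input_path)

        stage = "features"
        bands = None
        if config.bands is not None:
            from .features import BandDefinition

            bands = [BandDefinition(n, lo, hi) for n, (lo, hi) in config.bands.items()]
        table = zscore(
            extract_features(
                trials, bands=bands, window=config.window_seconds, overlap=config.overlap
            )
        )
        write_table(outdir / "features.tsv", feature_table_frame(table), config)
        sel, val = split_dataset(table, seed=config.seed)
        log.info("features: %d samples × %d features; split %d/%d samples",
                 table.n_samples, table.n_features, sel.n_samples, val.n_samples)

        stage = "rank"
        if config.method == "relieff":
            fw = relieff(sel, ReliefFConfig(k=config.relieff_k))
        elif config.method == "fscore":
            fw = fscore(sel)
        else:
            raise ValueError(f"unknown ranking method {config.method!r}")
        write_table(
            outdir / "weights.tsv",
            weights_frame(table.feature_names, fw.weights, fw.ranking),
            config,
        )

        stage = "select"
        clf = ClassifierSpec(cv_folds=config.cv_folds, cv_repeats=config.cv_repeats,
                             seed=config.seed)
        trace_frame = None
        if config.strategy == "topn-features":
            selection = channels_from_top_features(
                fw, sel.feature_channels, config.top_n_features
            ).selected
            cw = None
        elif config.strategy in ("mrcs", "xmrcs"):
            cw = mrcs(fw, sel.feature_channels, sel.n_channels, sel.channel_names)
            if config.strategy == "xmrcs":
                result = xmrcs(sel, cw, clf, config.epsilon, config.max_iterations)
                cw = result.channel_weights
                rows = []
                for st in result.trace:
                    for pos, ch in enumerate(st.ranking):
                        rows.append(
                            {
                                "iteration": st.iteration,
                                "rank": pos + 1,
                                "channel": sel.channel_names[ch],
                                "weight": st.weights[ch],
                                "S_n": st.curve[pos],
                                "C_n": st.contributions[pos],
                            }
                        )
                trace_frame = pd.DataFrame(rows)
                write_table(outdir / "trace.tsv", trace_frame, config)
            selection = [int(c) for c in cw.ranking]
        else:
            raise ValueError(f"unknown strategy {config.strategy!r}")
        if cw is not None:
            write_table(outdir / "channel_ranking.tsv", channel_ranking_frame(cw), config)

        stage = "validate"
        curve = validate_selection(
            selection, val, clf, selection_trials=sel.trial_of_sample
        )
        write_table(outdir / "curve.tsv", curve.as_frame(), config)

        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "strategy": config.strategy,
            "method": config.method,
            "n_samples": int(table.n_samples),
            "n_features": int(table.n_features),
            "selection": [int(c) for c in selection],
            "best_accuracy": float(curve.mean_accuracy.max()),
            "best_n": int(curve.n_selected[int(curve.mean_accuracy.argmax())]),
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("best mean accuracy %.4f at n=%d", report["best_accuracy"], report["best_n"])
        return {
            "table": table,
            "selection_table": sel,
            "validation_table": val,
            "feature_weights": fw,
            "channel_weights": cw,
            "selection": selection,
            "curve": curve,
            "trace": trace_frame,
            "report": report,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
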