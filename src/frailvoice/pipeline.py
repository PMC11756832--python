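"""End-to-end reproducible runs: simulate -> features -> pretrain -> train ->
evaluate -> compare -> report.

Every stage draws its randomness from seeds derived deterministically from the
master seed, so rerunning a config reproduces the metrics JSON byte for byte.
Artifacts live in a hash-named run directory (no timestamps): cohort manifest
and WAVs, functional-feature CSV, encoder and per-fold classifier checkpoints,
``metrics.json`` and a human-readable ``report.txt``.

Two profiles share all code paths: ``conformance`` builds the full-size
encoder whose parameter budget matches the published model, ``fast`` shrinks
the encoder, clip duration and pretraining corpus for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import cohort as ch
from . import features as ft
from . import models as md
from . import training as tr
from . import evaluation as ev

__all__ = [
    "RunConfig",
    "build_dataset",
    "cross_validate",
    "run_pipeline",
    "report",
    "recovery_experiment",
]

_STAGES = ("simulate", "features", "pretrain", "train", "evaluate", "compare", "report")


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for one pipeline run."""

    n: int = 127
    positive_prevalence: float = 65 / 127
    clip_duration: float = 4.0
    sample_rate: int = 48_000
    profile: str = "fast"
    k_folds: int = 5
    threshold: float = 0.5
    ssl_corpus_size: int = 48
    ssl_epochs: int = 6
    mask_fraction: float = 0.15
    target_prevalence: float = 0.20
    imbalanced_repeats: int = 20
    seed: int = 0
    outdir: str = "runs"

    def __post_init__(self) -> None:
        if self.profile not in ("conformance", "fast"):
            raise ValueError("profile must be 'conformance' or 'fast'")

    # -- seeds: all derived from the master seed, kept below 2**31 ----------

    def sub_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def run_dir(self) -> Path:
        return Path(self.outdir) / f"run-{self.config_hash()}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _audio_params(config: RunConfig) -> ch.AudioClassParams:
    return ch.AudioClassParams(
        duration=config.clip_duration, sample_rate=config.sample_rate
    )


def build_dataset(
    config: RunConfig, with_functionals: bool = True
) -> tuple[tr.CohortDataset, list[ch.Participant]]:
    """Simulate a cohort and extract frame features (and functionals) in memory."""
    spec = ch.CohortSpec(
        n=config.n,
        positive_prevalence=config.positive_prevalence,
        audio_params=_audio_params(config),
        seed=config.sub_seed("cohort"),
    )
    participants = ch.generate_cohort(spec)
    recordings = ch.synthesize_cohort_audio(
        participants, spec.audio_params, seed=config.sub_seed("audio")
    )
    fcfg = ft.FeatureConfig()
    feats = [ft.extract_mfcc_features(recordings[p.id], fcfg) for p in participants]
    funcs = (
        np.stack([ft.extract_functionals(recordings[p.id], fcfg) for p in participants])
        if with_functionals
        else None
    )
    dataset = tr.CohortDataset(
        ids=[p.id for p in participants],
        features=feats,
        ages=np.array([p.age for p in participants], dtype=float),
        sexes=[p.sex for p in participants],
        labels=np.array([p.label for p in participants], dtype=int),
        functionals=funcs,
    )
    return dataset, participants


def pretrain_encoder(
    config: RunConfig,
) -> tuple[dict[str, np.ndarray], list[float], md.SpeechEncoderModule]:
    """Build the SSL corpus and pretrain a speech encoder for this config."""
    sp_cfg, _, _ = md.assembly_configs("SpeechAI", config.profile)
    module = md.SpeechEncoderModule(sp_cfg, seed=config.sub_seed("encoder-init"))
    corpus = ch.generate_unlabeled_corpus(
        config.ssl_corpus_size, _audio_params(config), seed=config.sub_seed("corpus")
    )
    fcfg = ft.FeatureConfig()
    corpus_feats = [ft.extract_mfcc_features(r, fcfg) for r in corpus]
    ssl = tr.SSLConfig(
        mask_fraction=config.mask_fraction,
        epochs=config.ssl_epochs,
        seed=config.sub_seed("ssl"),
    )
    weights, trace = tr.pretrain_speech_embedding(corpus_feats, module, ssl)
    module.encoder.set_parameters(weights)
    return weights, trace, module


def _shared_speech_module(
    config: RunConfig, pretrained: dict[str, np.ndarray] | None
) -> md.SpeechEncoderModule:
    sp_cfg, _, _ = md.assembly_configs("SpeechAI", config.profile)
    module = md.SpeechEncoderModule(sp_cfg, seed=config.sub_seed("encoder-init"))
    if pretrained is not None:
        module.encoder.set_parameters(pretrained)
    return module


def cross_validate(
    kind: str,
    dataset: tr.CohortDataset,
    folds: ev.FoldSplit,
    config: RunConfig,
    pretrained: dict[str, np.ndarray] | None = None,
    speech_cache: dict[int, np.ndarray] | None = None,
    checkpoint_dir: Path | None = None,
    reuse: bool = False,
) -> tuple[ev.CVResult, list[np.ndarray], list[np.ndarray]]:
    """Balanced k-fold CV of one assembly kind; returns result + fold scores.

    The (frozen) speech encoder is shared across folds, so clip embeddings are
    computed once; only the classifier and demographic tables differ per fold.
    """
    sp_cfg, demo_cfg, clf_cfg = md.assembly_configs(kind, config.profile)
    speech = _shared_speech_module(config, pretrained) if sp_cfg else None
    if speech is not None and speech_cache is None:
        speech_cache = {
            i: speech.embed(dataset.features[i]) for i in range(len(dataset))
        }

    y = dataset.labels
    per_fold: list[ev.MetricSet] = []
    fold_scores: list[np.ndarray] = []
    fold_labels: list[np.ndarray] = []
    for f in range(folds.k):
        fold_seed = config.sub_seed(f"{kind}-fold{f}")
        rng = np.random.default_rng(fold_seed)
        demo = md.DemographicEmbedding(demo_cfg, seed=fold_seed) if demo_cfg else None
        clf = md.MLPHead(clf_cfg.input_dim, clf_cfg.hidden_dim, clf_cfg.n_classes, rng)
        assembly = md.ModelAssembly(kind, speech, demo, clf, clf_cfg)

        ckpt = (
            checkpoint_dir / f"{kind.lower()}-fold{f}.npz" if checkpoint_dir else None
        )
        if reuse and ckpt is not None and ckpt.exists():
            md.load_checkpoint(assembly, ckpt)
        else:
            ft_cfg = tr.FinetuneConfig(seed=fold_seed)
            tr.finetune(
                assembly,
                dataset,
                folds.train_indices(f),
                ft_cfg,
                speech_cache=speech_cache,
            )
            if ckpt is not None:
                md.save_checkpoint(assembly, ckpt, profile=config.profile)

        va = folds.fold_indices(f)
        p = tr.predict_proba(assembly, dataset, va, speech_cache=speech_cache)
        per_fold.append(ev.compute_metrics(p, y[va], config.threshold))
        fold_scores.append(p)
        fold_labels.append(y[va])
    return ev.summarize_metrics(kind, per_fold), fold_scores, fold_labels


def _pooled_out_of_fold(folds: ev.FoldSplit, fold_scores, n: int) -> np.ndarray:
    pooled = np.zeros(n)
    for f in range(folds.k):
        pooled[folds.fold_indices(f)] = fold_scores[f]
    return pooled


def run_pipeline(config: RunConfig, evaluation_only: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    With ``evaluation_only=True`` training stages are skipped and per-fold
    classifier checkpoints from a previous run of the same config are reused
    (an error is raised if they are missing).
    """
    run_dir = config.run_dir()
    ckpt_dir = run_dir / "checkpoints"
    run_dir.mkdir(parents=True, exist_ok=True)
    ckpt_dir.mkdir(exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    if evaluation_only:
        expected = [
            ckpt_dir / f"{kind.lower()}-fold{f}.npz"
            for kind in md.KINDS
            for f in range(config.k_folds)
        ]
        missing = [str(p.name) for p in expected if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"evaluation-only run but checkpoints missing: {missing}"
            )

    # simulate + features (always recomputed; deterministic from the seed)
    dataset, participants = build_dataset(config)
    ch.write_cohort(
        participants,
        run_dir / "cohort",
        base_params=_audio_params(config),
        seed=config.sub_seed("audio"),
    )
    ft.write_functionals_csv(
        run_dir / "functionals.csv", dataset.ids, dataset.functionals
    )

    folds = ev.make_balanced_folds(
        dataset.labels, k=config.k_folds, seed=config.sub_seed("folds")
    )

    # pretrain (skipped when reusing checkpoints: embeddings live in them)
    pretrained = None
    if not evaluation_only:
        pretrained, ssl_trace, _ = pretrain_encoder(config)
        np.savez(run_dir / "encoder-pretrained.npz", **pretrained)
        (run_dir / "ssl_loss_trace.csv").write_text(
            "epoch,heldout_masked_mse\n"
            + "\n".join(f"{i},{v:.8f}" for i, v in enumerate(ssl_trace))
        )
    elif (run_dir / "encoder-pretrained.npz").exists():
        with np.load(run_dir / "encoder-pretrained.npz") as z:
            pretrained = {k: z[k] for k in z.files}

    # train + evaluate the three assemblies
    cv_results: dict[str, ev.CVResult] = {}
    fold_score_map: dict[str, list[np.ndarray]] = {}
    fold_label_map: dict[str, list[np.ndarray]] = {}
    for kind in md.KINDS:
        res, scores, labels_ = cross_validate(
            kind,
            dataset,
            folds,
            config,
            pretrained=pretrained if kind != "DemoAI" else None,
            checkpoint_dir=ckpt_dir,
            reuse=evaluation_only,
        )
        cv_results[kind] = res
        fold_score_map[kind] = scores
        fold_label_map[kind] = labels_
        ev.plot_roc_curves(scores, labels_, kind, run_dir / f"roc-{kind.lower()}.png")
        ev.roc_points(np.concatenate(scores), np.concatenate(labels_)).to_csv(
            run_dir / f"roc-{kind.lower()}.csv", index=False
        )

    # classical baselines on functionals
    baselines = {
        kind: ev.train_baseline(
            kind, dataset.functionals, dataset.labels, folds,
            seed=config.sub_seed("baseline"),
        )
        for kind in ("logistic_regression", "decision_tree", "random_forest")
    }

    # pairwise fold-level AUC tests
    def aucs(kind: str) -> np.ndarray:
        return cv_results[kind].fold_values("auc")

    tests = {
        "SpeechAI_vs_DemoAI": ev.paired_auc_ttest(aucs("SpeechAI"), aucs("DemoAI")),
        "DemoSpeechAI_vs_DemoAI": ev.paired_auc_ttest(
            aucs("DemoSpeechAI"), aucs("DemoAI")
        ),
        "DemoSpeechAI_vs_SpeechAI": ev.paired_auc_ttest(
            aucs("DemoSpeechAI"), aucs("SpeechAI")
        ),
    }

    # prevalence-shifted sensitivity analysis on pooled out-of-fold scores
    pooled = _pooled_out_of_fold(folds, fold_score_map["SpeechAI"], len(dataset))
    imbalanced = ev.evaluate_imbalanced(
        pooled,
        dataset.labels,
        target_prevalence=config.target_prevalence,
        repeats=config.imbalanced_repeats,
        seed=config.sub_seed("imbalanced"),
    )
    imbalanced.pop("per_repeat")

    param_reports = {
        kind: asdict(md.count_parameters(md.build_assembly(kind, config.profile)))
        for kind in md.KINDS
    }

    metrics = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "profile": config.profile,
        "cv": {k: v.to_dict() for k, v in cv_results.items()},
        "baselines": {k: v.to_dict() for k, v in baselines.items()},
        "tests": {k: asdict(v) for k, v in tests.items()},
        "imbalanced_speechai": imbalanced,
        "param_reports": param_reports,
    }
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    (run_dir / "report.txt").write_text(report(run_dir))
    return run_dir


def report(run_directory: str | Path) -> str:
    """Human-readable summary of a completed run (tables of mean CI/min/max)."""
    run_directory = Path(run_directory)
    metrics_path = run_directory / "metrics.json"
    if not metrics_path.exists():
        raise FileNotFoundError(
            f"{run_directory} has no metrics.json; stages missing: run the pipeline first"
        )
    m = json.loads(metrics_path.read_text())

    def fmt_block(name: str, block: dict) -> list[str]:
        lines = [name]
        lines.append(f"  {'metric':<12}{'mean (95% CI)':>26}{'min':>9}{'max':>9}")
        for metric in ev.METRIC_NAMES:
            s = block["summaries"][metric]
            lines.append(
                f"  {metric:<12}{s['mean']:>10.2f} "
                f"({s['ci_low']:.2f}-{s['ci_high']:.2f}){'':>4}"
                f"{s['min']:>9.2f}{s['max']:>9.2f}"
            )
        return lines

    lines: list[str] = [f"Run {m['config_hash']} (profile {m['profile']}, seed {m['seed']})", ""]
    lines.append("Cross-validated model performance")
    for kind in md.KINDS:
        lines += fmt_block(kind, m["cv"][kind]) + [""]
    lines.append("Classical baselines on functional features")
    for kind, block in m["baselines"].items():
        lines += fmt_block(kind, block) + [""]
    lines.append("Paired fold-level AUC tests (df = k-1)")
    for name, t in m["tests"].items():
        lines.append(
            f"  {name}: t{t['df']}={t['t']:.3f}, two-sided p={t['p']:.4f}, "
            f"mean AUC difference {t['mean_difference']:+.3f}"
        )
    imb = m["imbalanced_speechai"]
    lines.append("")
    lines.append(
        "SpeechAI at shifted prevalence "
        f"{imb['achieved_prevalence']:.3f}"
        + ("" if imb["exact"] else " (nearest attainable below target)")
        + ": "
        + ", ".join(f"{k}={v:.3f}" for k, v in imb["metrics"].items())
    )
    return "\n".join(lines) + "\n"


def recovery_experiment_summary(runs: list[dict]) -> dict:
    """Aggregate mean AUCs across recovery runs (one entry per seed)."""
    keys = runs[0]["auc"].keys()
    return {k: float(np.mean([r["auc"][k] for r in runs])) for k in keys}


def recovery_experiment(
    seed: int,
    n: int = 200,
    profile: str = "fast",
    config: RunConfig | None = None,
) -> dict:
    """One synthetic-recovery run: CV AUCs for all kinds plus a random-backbone
    control and the paired AUC tests.  Used for the class-signal ordering and
    pretraining non-inferiority checks.
    """
    config = config or RunConfig(n=n, profile=profile, seed=seed, positive_prevalence=0.5)
    dataset, _ = build_dataset(config, with_functionals=False)
    folds = ev.make_balanced_folds(
        dataset.labels, k=config.k_folds, seed=config.sub_seed("folds")
    )
    pretrained, ssl_trace, _ = pretrain_encoder(config)

    out: dict = {"seed": seed, "n": n, "ssl_trace": ssl_trace}
    res_speech, *_ = cross_validate(
        "SpeechAI", dataset, folds, config, pretrained=pretrained
    )
    res_speech_rand, *_ = cross_validate(
        "SpeechAI", dataset, folds, config, pretrained=None
    )
    res_demo, *_ = cross_validate("DemoAI", dataset, folds, config)
    res_both, *_ = cross_validate(
        "DemoSpeechAI", dataset, folds, config, pretrained=pretrained
    )
    out["auc"] = {
        "SpeechAI": res_speech.summaries["auc"].mean,
        "SpeechAI_random_backbone": res_speech_rand.summaries["auc"].mean,
        "DemoAI": res_demo.summaries["auc"].mean,
        "DemoSpeechAI": res_both.summaries["auc"].mean,
    }
    out["accuracy"] = {
        "SpeechAI": res_speech.summaries["accuracy"].mean,
        "DemoAI": res_demo.summaries["accuracy"].mean,
        "DemoSpeechAI": res_both.summaries["accuracy"].mean,
    }
    out["tests"] = {
        "SpeechAI_vs_DemoAI": asdict(
            ev.paired_auc_ttest(
                res_speech.fold_values("auc"), res_demo.fold_values("auc")
            )
        ),
        "DemoSpeechAI_vs_SpeechAI": asdict(
            ev.paired_auc_ttest(
                res_both.fold_values("auc"), res_speech.fold_values("auc")
            )
        ),
    }
    return out
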