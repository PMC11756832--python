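"""Model/Results front end over the cross-validation protocol.

``FrailtyClassifierModel`` binds one assembly kind to a cohort dataset;
``fit()`` runs balanced k-fold cross-validation (with optional self-supervised
pretraining of the speech encoder) and returns a ``FrailtyClassifierResults``
carrying per-fold metrics, fold summaries with 95% CIs, and a ``summary()``
table.  ``compare()`` runs the paired fold-level AUC t-test between two fitted
results that share a fold split.
"""

from __future__ import annotations

import numpy as np

from . import evaluation as ev
from . import pipeline as pl
from . import training as tr
from .models import KINDS

__all__ = ["FrailtyClassifierModel", "FrailtyClassifierResults"]


class FrailtyClassifierResults:
    """Cross-validated results for one assembly kind."""

    def __init__(
        self,
        model: "FrailtyClassifierModel",
        cv_result: ev.CVResult,
        fold_scores: list[np.ndarray],
        fold_labels: list[np.ndarray],
        folds: ev.FoldSplit,
    ) -> None:
        self.model = model
        self.cv_result = cv_result
        self.fold_scores = fold_scores
        self.fold_labels = fold_labels
        self.folds = folds

    @property
    def per_fold(self) -> list[ev.MetricSet]:
        return self.cv_result.per_fold

    def fold_aucs(self) -> np.ndarray:
        return self.cv_result.fold_values("auc")

    def conf_int(self, metric: str) -> tuple[float, float]:
        s = self.cv_result.summaries[metric]
        return (s.ci_low, s.ci_high)

    def mean(self, metric: str) -> float:
        return self.cv_result.summaries[metric].mean

    def summary(self) -> str:
        return self.cv_result.summary()

    def compare(self, other: "FrailtyClassifierResults") -> ev.TestResult:
        """Paired fold-level AUC t-test (self minus other); requires shared folds."""
        if not np.array_equal(self.folds.assignments, other.folds.assignments):
            raise ValueError("results were not fitted on the same fold split")
        return ev.paired_auc_ttest(self.fold_aucs(), other.fold_aucs())

    def evaluate_imbalanced(
        self, target_prevalence: float = 0.20, repeats: int = 20, seed: int = 0
    ) -> dict:
        """Prevalence-shifted sensitivity analysis on pooled out-of-fold scores."""
        pooled = pl._pooled_out_of_fold(
            self.folds, self.fold_scores, len(self.model.dataset)
        )
        return ev.evaluate_imbalanced(
            pooled,
            self.model.dataset.labels,
            target_prevalence=target_prevalence,
            repeats=repeats,
            seed=seed,
        )


class FrailtyClassifierModel:
    """One assembly kind bound to a cohort dataset, fitted by cross-validation."""

    def __init__(
        self,
        dataset: tr.CohortDataset,
        kind: str = "DemoSpeechAI",
        profile: str = "fast",
        k: int = 5,
        seed: int = 0,
    ) -> None:
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        self.dataset = dataset
        self.kind = kind
        self.profile = profile
        self.k = k
        self.seed = seed
        self._config = pl.RunConfig(n=len(dataset), profile=profile, k_folds=k, seed=seed)

    @classmethod
    def from_config(
        cls, config: pl.RunConfig, kind: str = "DemoSpeechAI"
    ) -> "FrailtyClassifierModel":
        dataset, _ = pl.build_dataset(config, with_functionals=False)
        model = cls(dataset, kind=kind, profile=config.profile,
                    k=config.k_folds, seed=config.seed)
        model._config = config
        return model

    def fit(
        self,
        pretrain: bool = True,
        folds: ev.FoldSplit | None = None,
    ) -> FrailtyClassifierResults:
        """Run balanced k-fold CV; optionally SSL-pretrain the speech encoder."""
        config = self._config
        if folds is None:
            folds = ev.make_balanced_folds(
                self.dataset.labels, k=self.k, seed=config.sub_seed("folds")
            )
        pretrained = None
        if pretrain and self.kind != "DemoAI":
            pretrained, _, _ = pl.pretrain_encoder(config)
        cv_result, scores, labels = pl.cross_validate(
            self.kind, self.dataset, folds, config, pretrained=pretrained
        )
        return FrailtyClassifierResults(self, cv_result, scores, labels, folds)
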