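"""Model/Results interface over the genetic-folding kernel search.

`GeneticFoldingSVM` is constructed from data (arrays, a survey DataFrame,
or a survey CSV); `fit()` runs the evolutionary kernel search plus a final
precomputed-kernel SVM refit and returns a `GeneticFoldingResults` carrying
the evolved kernel, its cross-validated accuracy, the per-generation
history, and prediction/summary/plotting methods.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import data as _data
from .evolution import EvolutionConfig, EvolutionResult, evolve
from .kernel_lang import GramMatrix, gram, gram_unit_scale, repair_gram
from .svm_bridge import SVMConfig, TrainedModel, train_precomputed

__all__ = ["GeneticFoldingSVM", "GeneticFoldingResults"]


class GeneticFoldingSVM:
    """An SVM whose kernel function is evolved from the data.

    Parameters
    ----------
    endog : array-like of +-1 labels.
    exog : (n, d) feature matrix.  Pass raw (unscaled) features; the model
        standardizes internally and remembers the scaling for prediction.
    feature_names : optional column names.

    Examples
    --------
    >>> from genofold import GeneratorConfig, synthesize_survey
    >>> model = GeneticFoldingSVM.from_survey(synthesize_survey(GeneratorConfig(seed=7)))
    >>> res = model.fit(population_size=20, max_generations=5, seed=7)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, endog, exog, feature_names: Optional[Sequence[str]] = None):
        y = np.asarray(endog)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("exog must be (n, d) with one label per row")
        if set(np.unique(y)) - {-1, 1}:
            raise ValueError("endog must be coded +-1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self.endog = y.astype(int)
        self.exog = X
        self.feature_names = (
            tuple(feature_names)
            if feature_names
            else tuple(f"x{i}" for i in range(X.shape[1]))
        )
        self.nobs = X.shape[0]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_survey(cls, table: _data.SurveyTable) -> "GeneticFoldingSVM":
        ds = _data.preprocess(table)
        model = cls(ds.y, ds.raw, ds.feature_names)
        model._dropped_rows = ds.dropped_rows
        return model

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "GeneticFoldingSVM":
        return cls.from_survey(_data.SurveyTable(frame))

    @classmethod
    def from_survey_csv(cls, path) -> "GeneticFoldingSVM":
        return cls.from_survey(_data.read_survey_csv(path))

    # -- fitting ------------------------------------------------------------

    def fit(self, config: Optional[EvolutionConfig] = None, **kwargs) -> "GeneticFoldingResults":
        """Evolve a kernel and refit the final SVM on all rows.

        Keyword arguments override fields of :class:`EvolutionConfig`
        (e.g. ``population_size=50, max_generations=20, seed=0``).
        """
        cfg = config if config is not None else EvolutionConfig()
        if kwargs:
            cfg = replace(cfg, **kwargs)
        X, scaling, _ = _data.standardize(self.exog)
        dataset = _data.dataset_from_arrays(X, self.endog, self.feature_names)
        evo = evolve(dataset, cfg)
        expr = evo.best_expression
        G = gram(expr, X)
        kscale = gram_unit_scale((G.values + G.values.T) / 2.0)
        G = repair_gram(GramMatrix(G.values / kscale, valid=G.valid), cfg.repair)
        svm_cfg = SVMConfig(C=cfg.svm_C, class_weight=cfg.class_weight)
        trained = train_precomputed(G, self.endog, svm_cfg)
        return GeneticFoldingResults(self, cfg, evo, X, scaling, trained, kscale)


class GeneticFoldingResults:
    """Results of a genetic-folding kernel fit."""

    def __init__(self, model, config, evolution: EvolutionResult, X_scaled,
                 scaling, trained: TrainedModel, kernel_scale: float = 1.0):
        self.model = model
        self.config = config
        self.evolution = evolution
        self.best_chromosome = evolution.best.chromosome
        self.kernel = evolution.best_expression
        self.cv_accuracy = evolution.best.fitness
        self.complexity = evolution.best.complexity
        self.generations_run = evolution.generations_run
        self._X = X_scaled
        self._scaling = scaling
        self._trained = trained
        self._kernel_scale = kernel_scale
        self.train_accuracy = trained.train_accuracy

    # -- prediction ---------------------------------------------------------

    def _scale(self, X) -> np.ndarray:
        mean, sd = self._scaling
        return (np.asarray(X, dtype=float) - mean) / sd

    def decision_function(self, exog=None) -> np.ndarray:
        Xnew = self._X if exog is None else self._scale(exog)
        K = gram(self.kernel, Xnew, self._X).values / self._kernel_scale
        return self._trained.decision_function(K)

    def predict(self, exog=None) -> np.ndarray:
        """Predicted +-1 labels for new raw feature rows (default: training rows)."""
        Xnew = self._X if exog is None else self._scale(exog)
        K = gram(self.kernel, Xnew, self._X).values / self._kernel_scale
        return self._trained.predict(K)

    @property
    def history(self) -> pd.DataFrame:
        return self.evolution.history_frame()

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        width = 58
        lines = [
            "Genetic Folding SVM Results".center(width),
            "=" * width,
            f"{'No. observations:':<26}{self.model.nobs:<12}"
            f"{'CV folds:':<12}{cfg.cv_folds}",
            f"{'Population size:':<26}{cfg.population_size:<12}"
            f"{'Generations:':<12}{self.generations_run}",
            f"{'Mutation rate:':<26}{cfg.mutation_rate:<12}"
            f"{'Repair:':<12}{cfg.repair}",
            f"{'SVM cost C:':<26}{cfg.svm_C:<12}"
            f"{'Seed:':<12}{cfg.seed}",
            "-" * width,
            f"{'CV accuracy (fitness):':<26}{self.cv_accuracy:.4f}",
            f"{'Training accuracy:':<26}{self.train_accuracy:.4f}",
            f"{'Kernel complexity:':<26}{self.complexity}",
            f"Best kernel:  {self.kernel}",
            f"Chromosome:   {self.best_chromosome.to_text()}",
            "=" * width,
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Best/mean fitness per generation; returns the matplotlib Axes."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["generation"], h["best_fitness"], label="best fitness")
        ax.plot(h["generation"], h["mean_fitness"], label="mean fitness")
        ax.set_xlabel("generation")
        ax.set_ylabel("CV accuracy")
        ax.legend()
        return ax
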