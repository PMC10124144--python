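"""Headline modelling API: fit a marker-discovery model, get results.

:class:`MarkerDiscovery` bundles a dataset and a one-vs-all annotation
mask with the discovery protocol (negative downsampling to a target
positive fraction, stratified hold-out, boosted-tree fit, observational
Shapley explanation). Its :meth:`~MarkerDiscovery.fit` returns a
:class:`DiscoveryResults` carrying the fitted ensemble, held-out
performance, the pixel-by-feature attribution matrix, global scores and
the candidate-marker ranking, with plotting and reporting attached.

Example
-------
>>> from shapims import phantom
>>> from shapims.model import MarkerDiscovery
>>> model = MarkerDiscovery.from_phantom(phantom.demo_config(seed=1),
...                                      class_name="target")
>>> res = model.fit(seed=1)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import boosting, shap_maps, shapley
from .boosting import ClassificationMetrics, TrainingConfig, TreeEnsemble
from .ims_data import AnnotationMask, IMSDataset, SpatialImage, ion_image
from .phantom import PhantomConfig, generate_phantom


def stage_seeds(master_seed: int, n: int = 3) -> list[int]:
    """Deterministic per-stage seeds derived from one master seed.

    Uses numpy's SeedSequence spawning so stages are statistically
    independent yet individually reproducible; values are kept below 2^31.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class MarkerDiscovery:
    """Molecular-marker discovery for one tissue class of an IMS dataset.

    Parameters
    ----------
    dataset
        Peak-picked IMS dataset.
    mask
        One-vs-all annotation (POS / NEG / EXCLUDED) for the class of
        interest; needs at least one POS and one NEG pixel.
    training_config
        Boosting hyper-parameters; the shrinkage default is 0.3.
    eta
        Probability threshold for the class decision (default 0.5).
    pos_fraction
        Positive-class share after negative downsampling (default 0.25).
    test_fraction
        Held-out fraction for generalization assessment (default 0.25).
    explanation_scope
        "all_pixels" (default) explains every pixel, labeled or not;
        "labeled_only" restricts to the annotated subset.
    direction_threshold
        Rank-correlation cut for correlative/anticorrelative calls.
    """

    def __init__(self, dataset: IMSDataset, mask: AnnotationMask,
                 training_config: TrainingConfig | None = None,
                 eta: float = 0.5, pos_fraction: float = 0.25,
                 test_fraction: float = 0.25,
                 explanation_scope: str = "all_pixels",
                 direction_threshold: float = 0.3):
        if len(mask.labels) != dataset.n_pixels:
            raise ValueError("mask length does not match dataset pixel count")
        if explanation_scope not in ("all_pixels", "labeled_only"):
            raise ValueError("explanation_scope must be all_pixels or "
                             "labeled_only")
        if not 0.0 < eta < 1.0:
            raise ValueError("eta must be in (0, 1)")
        self.dataset = dataset
        self.mask = mask
        self.training_config = training_config or TrainingConfig()
        self.eta = eta
        self.pos_fraction = pos_fraction
        self.test_fraction = test_fraction
        self.explanation_scope = explanation_scope
        self.direction_threshold = direction_threshold

    @classmethod
    def from_phantom(cls, cfg: PhantomConfig, class_name: str,
                     **kwargs) -> "MarkerDiscovery":
        """Build a model from a synthetic phantom's class mask."""
        ds, masks, gt = generate_phantom(cfg)
        if class_name not in masks:
            raise KeyError(f"unknown phantom region {class_name!r}")
        model = cls(ds, masks[class_name], **kwargs)
        model.ground_truth = gt
        return model

    def fit(self, seed: int = 0) -> "DiscoveryResults":
        """Run the full discovery chain and return the results object.

        Stage seeds (downsampling, hold-out split, boosting) are derived
        deterministically from ``seed``.
        """
        s_down, s_split, s_train = stage_seeds(seed, 3)
        labeled = boosting.make_labels(self.mask)
        balanced = boosting.downsample_negatives(
            labeled, self.pos_fraction, s_down)
        train, test = boosting.split_holdout(
            balanced, self.test_fraction, s_split)
        cfg = replace(self.training_config, seed=s_train)
        ens = boosting.train_ensemble(self.dataset, train, cfg)

        pred = boosting.predict_class(
            ens, self.dataset.intensities[test.pixel_indices], self.eta)
        metrics = boosting.evaluate(pred, test.labels)

        scope = (None if self.explanation_scope == "all_pixels"
                 else labeled.pixel_indices)
        sm = shapley.ensemble_shapley(ens, self.dataset, pixels=scope)
        gs = shapley.global_shap_scores(sm)
        ranking = shapley.rank_features(gs, self.dataset.mz_values)
        return DiscoveryResults(
            model=self, seed=seed, ensemble=ens, train=train, test=test,
            metrics=metrics, shapley_matrix=sm, global_scores=gs,
            ranking=ranking,
        )


@dataclass
class DiscoveryResults:
    """Fitted classifier, held-out performance and Shapley explanation."""

    model: MarkerDiscovery
    seed: int
    ensemble: TreeEnsemble
    train: boosting.LabeledSubset
    test: boosting.LabeledSubset
    metrics: ClassificationMetrics
    shapley_matrix: shapley.ShapleyMatrix
    global_scores: shapley.GlobalScores
    ranking: shapley.FeatureRanking

    # -- prediction / explanation views ------------------------------------
    def prediction_image(self) -> SpatialImage:
        return boosting.prediction_image(
            self.ensemble, self.model.dataset, self.model.eta)

    def ion_image(self, feature_index: int) -> SpatialImage:
        return ion_image(self.model.dataset, feature_index)

    def shap_map(self, feature_index: int) -> SpatialImage:
        return shap_maps.shap_map(
            self.shapley_matrix, feature_index, self.model.dataset)

    def direction_call(self, feature_index: int) -> shap_maps.DirectionCall:
        return shap_maps.direction_call(
            self.model.dataset, self.shapley_matrix, feature_index,
            threshold=self.model.direction_threshold)

    def local_accuracy(self, tol: float = 1e-6) -> dict:
        return shapley.check_local_accuracy(
            self.shapley_matrix, self.ensemble, self.model.dataset, tol)

    def report_topk(self, k: int, outdir) -> dict:
        return shap_maps.report_topk(
            self.model.dataset, self.shapley_matrix, self.ranking, k,
            outdir, direction_threshold=self.model.direction_threshold)

    # -- summary -----------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        m = self.metrics
        ds = self.model.dataset
        def fmt(v):
            return "undefined" if v is None else f"{v:.4f}"
        lines = [
            "Marker discovery results",
            "=" * 64,
            f"dataset: {ds.name}  ({ds.n_pixels} pixels x "
            f"{ds.n_features} features)",
            f"class:   {self.model.mask.class_name}  "
            f"(train {len(self.train)}, test {len(self.test)}, "
            f"pos fraction {self.train.n_pos / len(self.train):.2f})",
            f"model:   {len(self.ensemble.trees)} trees, "
            f"shrinkage {self.ensemble.learning_rate}, "
            f"base log-odds {self.ensemble.base_prediction:+.4f}",
            "-" * 64,
            "held-out performance:",
            f"  balanced accuracy {fmt(m.balanced_accuracy)}   "
            f"precision {fmt(m.precision)}",
            f"  recall (sens.)    {fmt(m.recall)}   "
            f"specificity {fmt(m.specificity)}",
            "-" * 64,
            f"top {top} candidate markers by global SHAP score:",
            "  rank  feature      m/z    global score  direction",
        ]
        for rec in self.ranking.top(top).itertuples():
            call = self.direction_call(int(rec.feature_index))
            lines.append(
                f"  {rec.rank:4d}  {rec.feature_index:7d}  "
                f"{rec.mz:9.3f}  {rec.global_shap_score:12.4f}  "
                f"{call.verdict.lower()} ({call.association_statistic:+.2f})"
            )
        lines.append("=" * 64)
        return "\n".join(lines)
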