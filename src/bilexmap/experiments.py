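"""End-to-end synthetic convergence experiment.

Trains an ensemble of bilingual, monolingual, and ablated models on one
synthetic naming dataset and runs the convergence battery, mirroring the
qualitative comparisons of interest:

* cross-language similarity-profile correlation (Fisher-z): bilingual model
  vs. the paired monolingual models, and standard vs. no-lateral ablation;
* distances between translation-equivalent category centers
  (boundary-dependent and boundary-independent);
* indirect/direct center-distance ratios;
* typicality correlations for translation pairs;
* dominant-name accuracy against the group norms.

Problem sizes default to a desk-scale protocol: 73 objects x 68 features,
5 replicates per condition, 200 epochs with phase boundaries 20/40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import LetterTable, PhonemeTable
from .production import naming_accuracy
from .stats import (
    category_geometry,
    compare_group_correlations,
    fisher_z,
    indirect_direct_ratio,
    profile_correlation,
    similarity_profile,
    simulated_distribution_table,
    typicality_correlation,
)
from .synth import SynthConfig, generate_dataset
from .trainer import ModelState, TrainingConfig, train_model

__all__ = ["ConvergenceResult", "run_convergence_experiment", "dominant_pairs"]


def dominant_pairs(config: SynthConfig) -> list[tuple[str, str]]:
    """Translation-equivalent dominant-name pairs of the synthetic languages.

    The generator assigns names to categories round-robin, so category k's
    dominant name in each language is the word with index k; categories are
    aligned across languages by index.
    """
    lang_a, lang_b = config.languages
    k = min(config.categories)
    return [(f"{lang_a.lower()}{i:02d}", f"{lang_b.lower()}{i:02d}")
            for i in range(k)]


@dataclass
class ConvergenceResult:
    """Ensemble-level outcome of the convergence experiment."""

    n_replicates: int
    epochs: int
    n_objects: int
    profile_length: int
    # per-replicate cross-language profile correlations (r)
    r_bilingual: list[float] = field(default_factory=list)
    r_monolingual: list[float] = field(default_factory=list)
    r_no_lateral: list[float] = field(default_factory=list)
    # per-replicate Eq.-3 style Z statistics
    Z_bi_vs_mono: list[float] = field(default_factory=list)
    Z_bi_vs_nolateral: list[float] = field(default_factory=list)
    # center distances per replicate, averaged over translation pairs
    center_dist_bi_mean: list[float] = field(default_factory=list)
    center_dist_mono_mean: list[float] = field(default_factory=list)
    center_dist_bi_median: list[float] = field(default_factory=list)
    center_dist_mono_median: list[float] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)
    # typicality correlations averaged over pairs
    typ_r_bilingual: list[float] = field(default_factory=list)
    typ_r_monolingual: list[float] = field(default_factory=list)
    accuracy_a: list[float] = field(default_factory=list)
    accuracy_b: list[float] = field(default_factory=list)

    @property
    def mean_z_bilingual(self) -> float:
        return float(np.mean([fisher_z(r) for r in self.r_bilingual]))

    @property
    def mean_z_monolingual(self) -> float:
        return float(np.mean([fisher_z(r) for r in self.r_monolingual]))

    @property
    def mean_z_no_lateral(self) -> float:
        return float(np.mean([fisher_z(r) for r in self.r_no_lateral]))


def _cross_language_profiles(model: ModelState):
    lang_a, lang_b = model.languages
    pa = similarity_profile(simulated_distribution_table(model, lang_a))
    pb = similarity_profile(simulated_distribution_table(model, lang_b))
    return pa, pb


def run_convergence_experiment(
    seed: int = 0,
    n_replicates: int = 5,
    epochs: int = 200,
    synth_config: SynthConfig | None = None,
) -> ConvergenceResult:
    """Train the four-condition ensemble and collect the convergence measures."""
    synth_config = synth_config or SynthConfig(divergence=0.3, seed=seed)
    dataset, _ = generate_dataset(synth_config)
    lang_a, lang_b = synth_config.languages
    pairs = dominant_pairs(synth_config)
    names_a = [a for a, _ in pairs]
    names_b = [b for _, b in pairs]

    phoneme_table = PhonemeTable.load()
    letter_table = LetterTable.load()
    tables = dict(phoneme_table=phoneme_table, letter_table=letter_table)

    def cfg(condition: str, ablation: str = "none") -> TrainingConfig:
        return TrainingConfig.scaled(epochs, condition=condition,
                                     ablation=ablation,
                                     n_replicates=n_replicates)

    n_objects = synth_config.n_objects
    result = ConvergenceResult(
        n_replicates=n_replicates, epochs=epochs, n_objects=n_objects,
        profile_length=n_objects * (n_objects - 1) // 2,
    )

    for i in range(n_replicates):
        rep_seed = seed + 1000 * (i + 1)
        bi = train_model(dataset, cfg("bilingual"), rep_seed, **tables)
        mono_a = train_model(dataset, cfg("monolingual_A"), rep_seed + 1, **tables)
        mono_b = train_model(dataset, cfg("monolingual_B"), rep_seed + 2, **tables)
        nolat = train_model(dataset, cfg("bilingual", "no_lateral"), rep_seed + 3,
                            **tables)

        # --- cross-language profile correlations -------------------------
        bi_a, bi_b = _cross_language_profiles(bi)
        mono_pa = similarity_profile(simulated_distribution_table(mono_a, lang_a))
        mono_pb = similarity_profile(simulated_distribution_table(mono_b, lang_b))
        nl_a, nl_b = _cross_language_profiles(nolat)

        result.r_bilingual.append(profile_correlation(bi_a, bi_b).r)
        result.r_monolingual.append(profile_correlation(mono_pa, mono_pb).r)
        result.r_no_lateral.append(profile_correlation(nl_a, nl_b).r)
        result.Z_bi_vs_mono.append(
            compare_group_correlations(bi_a, bi_b, mono_pa, mono_pb).Z
        )
        result.Z_bi_vs_nolateral.append(
            compare_group_correlations(bi_a, bi_b, nl_a, nl_b).Z
        )

        # --- category-center geometry ------------------------------------
        geo_bi_a = category_geometry(bi, names_a, lang_a)
        geo_bi_b = category_geometry(bi, names_b, lang_b)
        geo_mono_a = category_geometry(mono_a, names_a, lang_a)
        geo_mono_b = category_geometry(mono_b, names_b, lang_b)

        d_bi_mean, d_mono_mean, d_bi_med, d_mono_med, ratios = [], [], [], [], []
        for na, nb in pairs:
            d_bi_mean.append(np.linalg.norm(
                geo_bi_a.center_mean[na] - geo_bi_b.center_mean[nb]))
            d_mono_mean.append(np.linalg.norm(
                geo_mono_a.center_mean[na] - geo_mono_b.center_mean[nb]))
            d_bi_med.append(np.linalg.norm(
                geo_bi_a.center_median[na] - geo_bi_b.center_median[nb]))
            d_mono_med.append(np.linalg.norm(
                geo_mono_a.center_median[na] - geo_mono_b.center_median[nb]))
            try:
                ratios.append(indirect_direct_ratio(
                    geo_mono_a.center_mean[na], geo_mono_b.center_mean[nb],
                    geo_bi_a.center_mean[na], geo_bi_b.center_mean[nb]))
            except ValueError:
                pass  # coincident monolingual centers: ratio undefined
        result.center_dist_bi_mean.append(float(np.mean(d_bi_mean)))
        result.center_dist_mono_mean.append(float(np.mean(d_mono_mean)))
        result.center_dist_bi_median.append(float(np.mean(d_bi_med)))
        result.center_dist_mono_median.append(float(np.mean(d_mono_med)))
        if ratios:
            result.ratios.append(float(np.mean(ratios)))

        # --- typicality correlations -------------------------------------
        typ_bi, typ_mono = [], []
        for na, nb in pairs:
            try:
                typ_bi.append(typicality_correlation((bi, bi), (na, nb)).r)
                typ_mono.append(
                    typicality_correlation((mono_a, mono_b), (na, nb)).r)
            except ValueError:
                pass  # zero-variance typicality vector in this replicate
        if typ_bi and typ_mono:
            result.typ_r_bilingual.append(float(np.mean(typ_bi)))
            result.typ_r_monolingual.append(float(np.mean(typ_mono)))

        # --- dominant-name accuracy --------------------------------------
        result.accuracy_a.append(naming_accuracy(bi, dataset, lang_a))
        result.accuracy_b.append(naming_accuracy(bi, dataset, lang_b))

    return result
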