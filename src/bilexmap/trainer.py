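"""Three-phase training protocol for the multi-layer naming model.

Phase 1 (epochs 0..hebbian_start): the semantic and phonological maps
self-organize independently.  Phase 2 (hebbian_start..reading_start): the
orthographic map starts training, agreement-scaled Hebbian learning links the
semantic map to the phonological map per language, and lateral connections
between co-activated cross-language name BMUs begin to grow.  Phase 3
(reading_start..total_epochs): semantic-orthographic and
phonological-orthographic Hebbian pathways join, simulating reading.

At full scale the boundaries are 50 / 100 / 500 epochs; conditions cover the
bilingual model, two monolingual models, and ablations without the
orthographic map or without lateral connections.  Ensembles of replicates
differ only in their seeds (base + i), matching the study's practice of
averaging over independently initialized simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GROUP_MONO_A, GROUP_MONO_B, NamingDataset
from .encoders import Lexeme, LetterTable, PhonemeTable, load_lexicon
from .hebbian import AssociativeMatrix, LateralMatrix
from .som import (
    MapGrid,
    NeighborhoodState,
    TrainingSchedule,
    adapt_radius,
    find_bmu,
    find_bmus,
    quantization_error,
    update_map,
)

__all__ = [
    "TrainingConfig",
    "ModelState",
    "train_model",
    "run_ensemble",
    "CONDITIONS",
    "ABLATIONS",
]

CONDITIONS = ("bilingual", "monolingual_A", "monolingual_B")
ABLATIONS = ("none", "no_orthography", "no_lateral")

MAP_SEMANTIC = "S"
MAP_PHONOLOGICAL = "P"
MAP_ORTHOGRAPHIC = "O"


@dataclass(frozen=True)
class TrainingConfig:
    """Protocol parameters for one training run."""

    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    hebbian_start: int = 50
    reading_start: int = 100
    condition: str = "bilingual"
    ablation: str = "none"
    n_replicates: int = 20
    base_seed: int = 0
    rows: int = 30
    cols: int = 40
    initial_radius: int = 15
    radius_floor: int = 1
    check_interval: int = 5
    ortho_spread_radius_floor: int = 3  # test-time orthographic spreading floor

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.schedule.total_epochs > 0 and not (
            0 < self.hebbian_start < self.reading_start <= self.schedule.total_epochs
        ):
            raise ValueError(
                "phase boundaries must satisfy 0 < hebbian_start < reading_start "
                "<= total_epochs"
            )

    @classmethod
    def scaled(cls, total_epochs: int, **kwargs) -> "TrainingConfig":
        """Config with phase boundaries scaled proportionally to a shorter run.

        The 50/100/500 protocol maps to total_epochs * (0.1, 0.2, 1); the
        learning-rate anneal window scales with the reading-start boundary,
        as it does at full scale.
        """
        hebbian_start = max(1, round(total_epochs * 0.1))
        reading_start = max(hebbian_start + 1, round(total_epochs * 0.2))
        schedule = TrainingSchedule(
            total_epochs=total_epochs, lr_anneal_epochs=reading_start
        )
        return cls(schedule=schedule, hebbian_start=hebbian_start,
                   reading_start=reading_start, **kwargs)


@dataclass
class ModelState:
    """Everything needed to run the naming task and the analysis battery."""

    config: TrainingConfig
    seed: int
    epoch: int
    languages: list[str]
    maps: dict[str, MapGrid]
    radius: dict[str, NeighborhoodState]
    assoc: dict[str, AssociativeMatrix]  # keys like 'S->P/A', 'S->O', 'P->O', 'O->P'
    lateral: LateralMatrix | None
    object_ids: list[str]
    features: np.ndarray  # (n_objects, F) semantic input vectors
    word_ids: list[str]
    word_langs: list[str]
    phon_vecs: np.ndarray
    orth_vecs: np.ndarray
    agreements: dict[str, np.ndarray]  # language -> (n_objects, n_words_lang)
    object_bmu: dict[str, int] = field(default_factory=dict)
    word_bmu_phon: dict[str, int] = field(default_factory=dict)
    word_bmu_orth: dict[str, int] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    rng_state: dict | None = None

    @property
    def has_orthography(self) -> bool:
        return MAP_ORTHOGRAPHIC in self.maps

    @property
    def has_lateral(self) -> bool:
        return self.lateral is not None

    def words_of(self, language: str) -> list[str]:
        return [w for w, l in zip(self.word_ids, self.word_langs) if l == language]

    def language_labeling(self) -> dict[int, str]:
        """Phonological BMU node -> language tag, assigned at test time only."""
        return {self.word_bmu_phon[w]: l
                for w, l in zip(self.word_ids, self.word_langs)}


def _condition_languages(condition: str, languages: list[str]) -> list[str]:
    if condition == "bilingual":
        return list(languages)
    if condition == "monolingual_A":
        return [languages[0]]
    return [languages[1]]


def _training_group(language: str, languages: list[str]) -> str:
    """Monolingual naming norms drive Hebbian agreement in every condition."""
    return GROUP_MONO_A if language == languages[0] else GROUP_MONO_B


def _refresh_registries(state: ModelState) -> None:
    s_bmus = find_bmus(state.maps[MAP_SEMANTIC], state.features)
    state.object_bmu = {o: int(b) for o, b in zip(state.object_ids, s_bmus)}
    p_bmus = find_bmus(state.maps[MAP_PHONOLOGICAL], state.phon_vecs)
    state.word_bmu_phon = {w: int(b) for w, b in zip(state.word_ids, p_bmus)}
    if state.has_orthography:
        o_bmus = find_bmus(state.maps[MAP_ORTHOGRAPHIC], state.orth_vecs)
        state.word_bmu_orth = {w: int(b) for w, b in zip(state.word_ids, o_bmus)}


def _bump_matrix(grid: MapGrid, centers: np.ndarray, radius: int) -> np.ndarray:
    """Stack of truncated-Gaussian bumps, one row per center node."""
    d2 = grid.grid_dist2()[centers]
    sigma = max(float(radius), 1.0)
    out = np.exp(-d2 / (2.0 * sigma * sigma))
    out[d2 > float(radius) ** 2] = 0.0
    return out


def _cap_rows(weights: np.ndarray) -> None:
    mx = weights.max(axis=1)
    over = mx > 1.0
    if over.any():
        weights[over] /= mx[over, None]


def _lateral_pass(
    state: ModelState, beta: float, langs: list[str]
) -> int:
    """One epoch of sparse lateral Hebbian growth between name BMUs.

    For every object, each pair of names it elicits across the two languages
    co-activates; the activation level of a name's BMU is taken to be its
    empirical agreement proportion, so both directed weights between the two
    BMUs grow by beta * N_a * N_b, followed by the multiplicative cap.
    Pairs whose BMUs collide on the same node are skipped (no
    self-connections).
    """
    lat = state.lateral
    lang_a, lang_b = langs
    words_a = state.words_of(lang_a)
    words_b = state.words_of(lang_b)
    agr_a = state.agreements[lang_a]
    agr_b = state.agreements[lang_b]
    touched: set[int] = set()
    n_updates = 0
    for i in range(len(state.object_ids)):
        ia = np.nonzero(agr_a[i])[0]
        ib = np.nonzero(agr_b[i])[0]
        for a in ia:
            na = agr_a[i, a]
            bmu_a = state.word_bmu_phon[words_a[a]]
            for b in ib:
                bmu_b = state.word_bmu_phon[words_b[b]]
                if bmu_a == bmu_b:
                    continue
                inc = beta * na * agr_b[i, b]
                lat.weights[(bmu_a, bmu_b)] = lat.get(bmu_a, bmu_b) + inc
                lat.weights[(bmu_b, bmu_a)] = lat.get(bmu_b, bmu_a) + inc
                touched.update((bmu_a, bmu_b))
                n_updates += 1
    lat._cap(touched)
    return n_updates


def train_model(
    dataset: NamingDataset,
    config: TrainingConfig,
    seed: int,
    phoneme_table: PhonemeTable | None = None,
    letter_table: LetterTable | None = None,
) -> ModelState:
    """Train one model replicate under the given condition and ablation."""
    dataset.check_consistency()
    phoneme_table = phoneme_table or PhonemeTable.load()
    letter_table = letter_table or LetterTable.load()

    languages = dataset.languages
    if len(languages) < 2 and config.condition == "bilingual":
        raise ValueError("bilingual condition needs two languages in the lexicon")
    cond_langs = _condition_languages(config.condition, languages)

    lex_df = dataset.lexicon[dataset.lexicon["language"].isin(cond_langs)]
    lexemes: list[Lexeme] = load_lexicon(lex_df, phoneme_table, letter_table)

    object_ids = dataset.object_ids
    features = dataset.feature_matrix()
    word_ids = [lx.word_id for lx in lexemes]
    word_langs = [lx.language for lx in lexemes]
    phon_vecs = np.array([lx.phon_vec for lx in lexemes])
    orth_vecs = np.array([lx.orth_vec for lx in lexemes])

    agreements = {
        lang: dataset.agreements(_training_group(lang, languages), lang).to_numpy()
        for lang in cond_langs
    }

    rng = np.random.default_rng(seed)
    use_ortho = config.ablation != "no_orthography"
    use_lateral = (
        config.ablation != "no_lateral" and config.condition == "bilingual"
    )

    n_nodes = config.rows * config.cols
    maps = {
        MAP_SEMANTIC: MapGrid.initialize(features.shape[1], config.rows, config.cols, rng),
        MAP_PHONOLOGICAL: MapGrid.initialize(phon_vecs.shape[1], config.rows, config.cols, rng),
    }
    if use_ortho:
        maps[MAP_ORTHOGRAPHIC] = MapGrid.initialize(
            orth_vecs.shape[1], config.rows, config.cols, rng
        )
    radius = {
        tag: NeighborhoodState(
            radius=config.initial_radius,
            radius_floor=config.radius_floor,
            check_interval=config.check_interval,
        )
        for tag in maps
    }
    assoc = {}
    for lang in cond_langs:
        assoc[f"S->P/{lang}"] = AssociativeMatrix.zeros(
            MAP_SEMANTIC, MAP_PHONOLOGICAL, lang, n_nodes, n_nodes
        )
    if use_ortho:
        assoc["S->O"] = AssociativeMatrix.zeros(
            MAP_SEMANTIC, MAP_ORTHOGRAPHIC, "shared", n_nodes, n_nodes
        )
        assoc["P->O"] = AssociativeMatrix.zeros(
            MAP_PHONOLOGICAL, MAP_ORTHOGRAPHIC, "shared", n_nodes, n_nodes
        )
        assoc["O->P"] = AssociativeMatrix.zeros(
            MAP_ORTHOGRAPHIC, MAP_PHONOLOGICAL, "shared", n_nodes, n_nodes
        )

    state = ModelState(
        config=config,
        seed=seed,
        epoch=0,
        languages=cond_langs,
        maps=maps,
        radius=radius,
        assoc=assoc,
        lateral=LateralMatrix() if use_lateral else None,
        object_ids=object_ids,
        features=features,
        word_ids=word_ids,
        word_langs=word_langs,
        phon_vecs=phon_vecs,
        orth_vecs=orth_vecs,
        agreements=agreements,
    )

    beta = config.schedule.hebbian_lr
    words_by_lang = {
        lang: np.array([i for i, l in enumerate(word_langs) if l == lang])
        for lang in cond_langs
    }

    for epoch in range(config.schedule.total_epochs):
        lr = config.schedule.lr(epoch)
        counts = {"hebbian_sp": 0, "hebbian_so": 0, "hebbian_po": 0, "lateral": 0}

        # --- self-organization -------------------------------------------
        plan = [(MAP_SEMANTIC, features), (MAP_PHONOLOGICAL, phon_vecs)]
        if use_ortho and epoch >= config.hebbian_start:
            plan.append((MAP_ORTHOGRAPHIC, orth_vecs))
        for tag, X in plan:
            grid = maps[tag]
            r = radius[tag].radius
            for idx in rng.permutation(X.shape[0]):
                x = X[idx]
                update_map(grid, x, find_bmu(grid, x), lr, r)
            radius[tag].record(quantization_error(grid, X))
            k = config.check_interval
            if (
                len(radius[tag].qe_history) >= 2 * k
                and len(radius[tag].qe_history) % k == 0
            ):
                adapt_radius(radius[tag])

        # --- Hebbian phases ----------------------------------------------
        if epoch >= config.hebbian_start:
            _refresh_registries(state)
            s_centers = np.array([state.object_bmu[o] for o in object_ids])
            s_bumps = _bump_matrix(maps[MAP_SEMANTIC], s_centers,
                                   radius[MAP_SEMANTIC].radius)
            p_centers = np.array([state.word_bmu_phon[w] for w in word_ids])
            p_bumps = _bump_matrix(maps[MAP_PHONOLOGICAL], p_centers,
                                   radius[MAP_PHONOLOGICAL].radius)
            for lang in cond_langs:
                widx = words_by_lang[lang]
                target = agreements[lang] @ p_bumps[widx]
                m = assoc[f"S->P/{lang}"].weights
                m += beta * (s_bumps.T @ target)
                _cap_rows(m)
                counts["hebbian_sp"] += int((agreements[lang] > 0).sum())
            if use_lateral:
                counts["lateral"] = _lateral_pass(state, beta, cond_langs)

        if epoch >= config.reading_start and use_ortho:
            o_centers = np.array([state.word_bmu_orth[w] for w in word_ids])
            o_bumps = _bump_matrix(maps[MAP_ORTHOGRAPHIC], o_centers,
                                   radius[MAP_ORTHOGRAPHIC].radius)
            target_o = np.zeros((len(object_ids), n_nodes))
            for lang in cond_langs:
                widx = words_by_lang[lang]
                target_o += agreements[lang] @ o_bumps[widx]
                counts["hebbian_so"] += int((agreements[lang] > 0).sum())
            m = assoc["S->O"].weights
            m += beta * (s_bumps.T @ target_o)
            _cap_rows(m)
            # phonology <-> orthography is a one-to-one pairing per word
            m = assoc["P->O"].weights
            m += beta * (p_bumps.T @ o_bumps)
            _cap_rows(m)
            m = assoc["O->P"].weights
            m += beta * (o_bumps.T @ p_bumps)
            _cap_rows(m)
            counts["hebbian_po"] += len(word_ids)

        state.epoch = epoch + 1
        state.log.append({
            "epoch": epoch,
            "lr": lr,
            "qe": {tag: radius[tag].qe_history[-1] for tag in maps
                   if radius[tag].qe_history},
            "radius": {tag: radius[tag].radius for tag in maps},
            "updates": counts,
        })

    _refresh_registries(state)
    state.rng_state = rng.bit_generator.state
    return state


def run_ensemble(
    dataset: NamingDataset,
    config: TrainingConfig,
    phoneme_table: PhonemeTable | None = None,
    letter_table: LetterTable | None = None,
) -> list[ModelState]:
    """Train n_replicates models with seeds base_seed + i."""
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    phoneme_table = phoneme_table or PhonemeTable.load()
    letter_table = letter_table or LetterTable.load()
    return [
        train_model(dataset, config, config.base_seed + i,
                    phoneme_table=phoneme_table, letter_table=letter_table)
        for i in range(config.n_replicates)
    ]
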