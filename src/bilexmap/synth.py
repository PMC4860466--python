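"""Synthetic bilingual naming-norm generator.

Emulates the structure of household-container naming norms: a stimulus table
of objects x semantic features (rater proportions in [0, 1]), a pseudo-word
lexicon per language, and per-group naming responses (monolingual group per
language plus a bilingual group naming in both languages).

Generative story: a small set of latent category prototypes (binary feature
vectors) defines language A's categories; language B's prototypes are the
same vectors with a fraction ``divergence`` of features flipped, so the two
languages draw category boundaries in (mis)aligned places.  Objects are noisy
copies of prototypes, re-rated by a panel of simulated raters.  A group names
an object by a softmax over (negative) feature-space distances to its
language's prototypes at temperature ``kappa``, then distributes probability
over that category's name pool (one dominant name plus a few object-specific
low-frequency names); participants are multinomial draws.  The bilingual
group's category probabilities are a fixed mixture of the A- and B-derived
probabilities, which makes the convergence expected of bilinguals part of the
known ground truth rather than an output of the network model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dataset import (
    GROUP_BILINGUAL,
    GROUP_MONO_A,
    GROUP_MONO_B,
    NamingDataset,
)

__all__ = [
    "SynthConfig",
    "generate_objects",
    "generate_lexicons",
    "generate_naming",
    "generate_dataset",
]

_CONSONANTS = "ptkbdfsmnlr"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic naming-norm generator.

    Defaults mirror the empirical study conditions: 73 objects, 68 features,
    3 frequent category names per language, name inventories of 42 and 39
    (including low-frequency names), 25 participants per group, and each
    object attracting 1-9 distinct names.
    """

    n_objects: int = 73
    n_features: int = 68
    categories: tuple[int, int] = (3, 3)
    n_names: tuple[int, int] = (42, 39)
    divergence: float = 0.3  # fraction of prototype features flipped for language B
    kappa: float = 0.1  # softmax temperature over prototype distances
    participants: int = 25
    cognate_fraction: float = 0.15
    flip_noise: float = 0.1  # per-feature flip probability for object vectors
    n_raters: int = 12  # simulated yes/no raters per feature
    bilingual_mix: float = 0.5  # weight of own-language probabilities for bilinguals
    boundary_mix: float = 0.5  # max graded-membership pull toward a second category
    dominant_share: float = 0.75  # name-probability mass on the category's dominant name
    low_freq_names_per_object: int = 2
    languages: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self):
        for name in ("divergence", "cognate_fraction", "flip_noise",
                     "bilingual_mix", "boundary_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        for name in ("n_objects", "n_features", "participants", "n_raters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.categories) < 1 or min(self.n_names) < max(self.categories):
            raise ValueError("each language needs at least one name per category")

    def to_dict(self) -> dict:
        return asdict(self)


def _prototypes(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent binary prototypes for each language's categories."""
    k_a, k_b = config.categories
    f = config.n_features
    if max(k_a, k_b) > 2 ** f:
        raise ValueError("more categories than representable binary prototypes")
    seen: set[bytes] = set()
    protos = []
    while len(protos) < k_a:
        p = rng.integers(0, 2, size=f)
        if p.tobytes() not in seen:
            seen.add(p.tobytes())
            protos.append(p)
    proto_a = np.array(protos, dtype=float)
    # language B prototypes: cycled copies of A's with a `divergence` fraction
    # of features flipped -> misaligned category boundaries
    n_flip = int(round(config.divergence * f))
    proto_b = proto_a[np.arange(k_b) % k_a].copy()
    for row in proto_b:
        flip = rng.choice(f, size=n_flip, replace=False)
        row[flip] = 1.0 - row[flip]
    return proto_a, proto_b


def generate_objects(config: SynthConfig, rng: np.random.Generator | None = None):
    """Stimulus table plus the latent prototypes used downstream.

    Each object starts from its category prototype; a per-object graded
    membership draw (uniform in [0, boundary_mix]) swaps that fraction of
    features toward a second category's prototype, producing the spread from
    core to boundary exemplars that real naming norms show.  Per-feature flip
    noise is then applied and the vector is re-expressed as rater
    proportions: every feature value is the fraction of ``n_raters``
    simulated raters answering yes, where a rater says yes with probability
    1 - flip_noise when the bit is on and flip_noise when it is off.  With
    boundary_mix = 0 and zero noise objects equal their prototypes exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    proto_a, proto_b = _prototypes(config, rng)
    k_a = config.categories[0]
    labels = np.arange(config.n_objects) % k_a
    bits = proto_a[labels].copy()
    if config.boundary_mix > 0 and k_a > 1:
        lam = rng.uniform(0.0, config.boundary_mix, size=config.n_objects)
        secondary = (labels + rng.integers(1, k_a, size=config.n_objects)) % k_a
        swap = rng.random(bits.shape) < lam[:, None]
        bits[swap] = proto_a[secondary][swap]
    p_yes = np.abs(bits - config.flip_noise)
    values = rng.binomial(config.n_raters, p_yes) / config.n_raters
    stimuli = pd.DataFrame(
        values, columns=[f"f{i}" for i in range(config.n_features)]
    )
    stimuli.insert(0, "object_id", [f"obj{i:03d}" for i in range(config.n_objects)])
    return stimuli, proto_a, proto_b, labels


def _make_word(rng: np.random.Generator) -> str:
    """A 2-3 syllable CV(C) pseudo-word that fits both slot templates."""
    n_syll = int(rng.integers(2, 4))
    parts = []
    for _ in range(n_syll):
        parts.append(rng.choice(list(_CONSONANTS)))
        parts.append(rng.choice(list(_VOWELS)))
    if rng.random() < 0.3:
        parts.append(rng.choice(list(_CONSONANTS)))
    return "".join(parts)


def generate_lexicons(config: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pseudo-word lexicons for both languages as one table.

    A ``cognate_fraction`` of paired names (matched by index across the two
    inventories) share their spelling and phonology exactly; all forms encode
    without template overflow since they are strict CV(C) strings.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lang_a, lang_b = config.languages
    n_a, n_b = config.n_names
    n_pairs = min(n_a, n_b)
    n_cognates = int(round(config.cognate_fraction * n_pairs))

    forms: set[str] = set()

    def fresh_word() -> str:
        for _ in range(10000):
            w = _make_word(rng)
            if w not in forms:
                forms.add(w)
                return w
        raise RuntimeError("requested word count unreachable without duplicates")

    forms_a = [fresh_word() for _ in range(n_a)]
    forms_b = [forms_a[i] if i < n_cognates else fresh_word() for i in range(n_b)]

    rows = []
    for i, form in enumerate(forms_a):
        rows.append(dict(word=f"{lang_a.lower()}{i:02d}", language=lang_a,
                         ipa=form, spelling=form))
    for i, form in enumerate(forms_b):
        rows.append(dict(word=f"{lang_b.lower()}{i:02d}", language=lang_b,
                         ipa=form, spelling=form))
    return pd.DataFrame(rows)


def _category_probs(features: np.ndarray, protos: np.ndarray, kappa: float) -> np.ndarray:
    """Softmax over negative Euclidean prototype distances at temperature kappa."""
    d = np.sqrt(((features[:, None, :] - protos[None, :, :]) ** 2).sum(axis=-1))
    logits = -d / kappa
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _name_pools(
    n_names: int, n_categories: int, words: list[str],
) -> list[list[str]]:
    """Partition a language's words into per-category pools; pool i's first
    entry is the category's dominant name."""
    pools: list[list[str]] = [[] for _ in range(n_categories)]
    for i, w in enumerate(words):
        pools[i % n_categories].append(w)
    return pools


def generate_naming(
    config: SynthConfig,
    stimuli: pd.DataFrame,
    lexicon: pd.DataFrame,
    proto_a: np.ndarray,
    proto_b: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial naming responses for the three groups.

    Per object the name distribution concentrates ``dominant_share`` of a
    category's mass on its dominant name and spreads the rest over a small
    object-specific subset of the category's low-frequency names, so that
    each object attracts between 1 and 9 distinct names under the defaults.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lang_a, lang_b = config.languages
    feats = stimuli[[c for c in stimuli.columns if c.startswith("f")]].to_numpy(float)
    words = {
        lang: lexicon[lexicon["language"] == lang]["word"].tolist()
        for lang in (lang_a, lang_b)
    }
    pools = {
        lang_a: _name_pools(config.n_names[0], config.categories[0], words[lang_a]),
        lang_b: _name_pools(config.n_names[1], config.categories[1], words[lang_b]),
    }
    cat_probs = {
        lang_a: _category_probs(feats, proto_a, config.kappa),
        lang_b: _category_probs(feats, proto_b, config.kappa),
    }
    k_a, k_b = config.categories
    k = min(k_a, k_b)

    def name_probs(lang: str, cat_p: np.ndarray, obj_rng: np.random.Generator) -> dict[str, float]:
        probs: dict[str, float] = {}
        for c, pc in enumerate(cat_p):
            if pc < 1e-9:
                continue
            pool = pools[lang][c]
            dom, rest = pool[0], pool[1:]
            probs[dom] = probs.get(dom, 0.0) + pc * config.dominant_share
            m = min(config.low_freq_names_per_object, len(rest))
            if m == 0:
                probs[dom] += pc * (1 - config.dominant_share)
                continue
            chosen = obj_rng.choice(len(rest), size=m, replace=False)
            for j in chosen:
                probs[rest[j]] = probs.get(rest[j], 0.0) + pc * (1 - config.dominant_share) / m
        total = sum(probs.values())
        return {w: p / total for w, p in probs.items()}

    rows = []
    mix = config.bilingual_mix
    for i in range(len(feats)):
        obj = stimuli["object_id"].iloc[i]
        # the bilingual group's category beliefs blend both languages' boundaries
        pa, pb = cat_probs[lang_a][i], cat_probs[lang_b][i]
        blended_a = mix * pa + (1 - mix) * np.append(pb[:k], np.zeros(k_a - k))
        blended_b = mix * pb + (1 - mix) * np.append(pa[:k], np.zeros(k_b - k))
        blended_a /= blended_a.sum()
        blended_b /= blended_b.sum()
        per_group = [
            (GROUP_MONO_A, lang_a, pa),
            (GROUP_MONO_B, lang_b, pb),
            (GROUP_BILINGUAL, lang_a, blended_a),
            (GROUP_BILINGUAL, lang_b, blended_b),
        ]
        # one low-frequency-name subset per object & language, shared across
        # groups, so group differences come from category probabilities alone
        obj_seeds = {lang_a: rng.integers(2 ** 31), lang_b: rng.integers(2 ** 31)}
        for group, lang, cat_p in per_group:
            probs = name_probs(lang, cat_p, np.random.default_rng(obj_seeds[lang]))
            names = list(probs)
            counts = rng.multinomial(config.participants, [probs[w] for w in names])
            for w, c in zip(names, counts):
                if c > 0:
                    rows.append(dict(object=obj, group=group, language=lang,
                                     name=w, count=int(c)))
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig) -> tuple[NamingDataset, dict]:
    """Full synthetic dataset plus a manifest describing how it was made."""
    rng = np.random.default_rng(config.seed)
    stimuli, proto_a, proto_b, labels = generate_objects(config, rng)
    lexicon = generate_lexicons(config, rng)
    responses = generate_naming(config, stimuli, lexicon, proto_a, proto_b, rng)
    ds = NamingDataset(stimuli=stimuli, lexicon=lexicon, responses=responses)
    ds.check_consistency()
    manifest = {
        "generator": "bilexmap.synth",
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.to_dict().items()},
        "latent_category_labels": labels.tolist(),
    }
    return ds, manifest
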