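"""The three-table bilingual naming dataset.

* stimuli — one row per object: an identifier plus semantic feature values in
  [0, 1] (proportion of raters affirming each feature);
* lexicon — one row per word form: word, language, IPA string, spelling;
* responses — naming-norm counts: object, language group, language, name,
  count of participants who produced that name.

Groups follow the study design: two monolingual groups (one per language) and
one bilingual group that names in both languages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NamingDataset", "GROUP_MONO_A", "GROUP_MONO_B", "GROUP_BILINGUAL"]

GROUP_MONO_A = "mono_A"
GROUP_MONO_B = "mono_B"
GROUP_BILINGUAL = "bilingual"

_FEATURE_PREFIX = "f"


@dataclass
class NamingDataset:
    """Container tying the stimulus, lexicon, and response tables together."""

    stimuli: pd.DataFrame  # object_id + feature columns f0..f{F-1}
    lexicon: pd.DataFrame  # word, language, ipa, spelling
    responses: pd.DataFrame  # object, group, language, name, count

    def __post_init__(self):
        if "object_id" not in self.stimuli.columns:
            raise ValueError("stimulus table needs an object_id column")
        for col in ("word", "language", "ipa", "spelling"):
            if col not in self.lexicon.columns:
                raise ValueError(f"lexicon table missing column {col!r}")
        for col in ("object", "group", "language", "name", "count"):
            if col not in self.responses.columns:
                raise ValueError(f"response table missing column {col!r}")

    # ------------------------------------------------------------- access
    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.stimuli.columns if c.startswith(_FEATURE_PREFIX)
                and c[len(_FEATURE_PREFIX):].isdigit()]

    @property
    def object_ids(self) -> list[str]:
        return self.stimuli["object_id"].astype(str).tolist()

    @property
    def languages(self) -> list[str]:
        return sorted(self.lexicon["language"].unique())

    def feature_matrix(self) -> np.ndarray:
        """(n_objects, n_features) array of rater-proportion feature values."""
        return self.stimuli[self.feature_columns].to_numpy(dtype=float)

    def words(self, language: str) -> list[str]:
        sub = self.lexicon[self.lexicon["language"] == language]
        return sub["word"].astype(str).tolist()

    def agreements(self, group: str, language: str) -> pd.DataFrame:
        """Name-agreement proportions for one group naming in one language.

        Returns a (n_objects x n_names) frame indexed by object, columns the
        language's full name inventory, each row summing to 1 (or 0 when the
        object drew no responses in this group).
        """
        sub = self.responses[
            (self.responses["group"] == group)
            & (self.responses["language"] == language)
        ]
        table = (
            sub.pivot_table(index="object", columns="name", values="count",
                            aggfunc="sum", fill_value=0.0)
            .reindex(index=self.object_ids, fill_value=0.0)
            .reindex(columns=self.words(language), fill_value=0.0)
            .astype(float)
        )
        totals = table.sum(axis=1)
        nonzero = totals > 0
        table.loc[nonzero] = table.loc[nonzero].div(totals[nonzero], axis=0)
        return table

    # -------------------------------------------------------- validation
    def check_consistency(self) -> None:
        """Raise if any response references an unknown object or name."""
        known_objects = set(self.object_ids)
        bad_obj = set(self.responses["object"].astype(str)) - known_objects
        if bad_obj:
            raise ValueError(f"responses reference unknown objects: {sorted(bad_obj)[:5]}")
        by_lang = {
            lang: set(self.words(lang)) for lang in self.languages
        }
        for lang, grp in self.responses.groupby("language"):
            if lang not in by_lang:
                raise ValueError(f"responses reference unknown language {lang!r}")
            orphan = set(grp["name"].astype(str)) - by_lang[lang]
            if orphan:
                raise ValueError(
                    f"responses in language {lang!r} use names missing from its "
                    f"lexicon: {sorted(orphan)[:5]}"
                )

    # --------------------------------------------------------------- io
    def save(self, directory: str | Path, manifest: dict | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.stimuli.to_csv(d / "stimuli.csv", index=False)
        self.lexicon.to_csv(d / "lexicon.csv", index=False)
        self.responses.to_csv(d / "responses.csv", index=False)
        if manifest is not None:
            (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "NamingDataset":
        d = Path(directory)
        return cls(
            stimuli=pd.read_csv(d / "stimuli.csv"),
            lexicon=pd.read_csv(d / "lexicon.csv"),
            responses=pd.read_csv(d / "responses.csv"),
        )
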