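"""Dataset curation and grouped, stratified 5-fold splitting.

Curation merges weights, assignments and per-frame features into the final
analysis dataset, dropping (in this order, one logged reason per specimen):

1. ``unassigned``      — no species-level taxonomic assignment,
2. ``below_detection`` — measured dry mass <= 0 mg (balance readings can be
   zero or negative near the detection limit),
3. ``rare_species``    — species with fewer than ``min_specimens_per_species``
   remaining specimens (so each species can appear in every fold),
4. ``no_clean_frames`` — every frame flagged as non-target.

Splits are stratified by species with the specimen as the non-overlapping
group: all frames of a specimen live in exactly one of train / validation /
test within a fold. Test sets across the k folds partition the curated
specimens; validation rotates one non-test fold. The same folds serve both
the species-identification and the biomass task, keeping results comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from sklearn.model_selection import StratifiedKFold

EXCLUSION_REASONS = ("unassigned", "below_detection", "rare_species", "no_clean_frames")


class EmptyDatasetError(ValueError):
    """Raised when curation removes every specimen."""


class InvalidDatasetError(ValueError):
    """Raised when a dataset cannot satisfy the fold invariants."""


@dataclass
class CuratedDataset:
    """Curated specimens (species-resolved, weighed) with their clean frames."""

    specimens: pd.DataFrame  # specimen_id, order, family, genus, species, mass_mg
    features: pd.DataFrame  # per-frame rows incl. nontarget_flag, restricted to curated specimens
    exclusion_log: pd.DataFrame  # specimen_id, reason

    @property
    def species(self) -> list[str]:
        return sorted(self.specimens["species"].unique())

    def clean_frames(self) -> pd.DataFrame:
        return self.features[~self.features["nontarget_flag"].astype(bool)]

    def taxonomy_map(self, rank: str) -> dict[str, str]:
        """species -> ancestor name at the requested rank."""
        cols = self.specimens[["species", rank]].drop_duplicates()
        return dict(zip(cols["species"], cols[rank]))


@dataclass
class FoldSplit:
    k: int
    seed: int
    test_sets: list[list[str]]  # fold index -> test specimen ids

    def test(self, i: int) -> list[str]:
        return list(self.test_sets[i])

    def validation(self, i: int) -> list[str]:
        return list(self.test_sets[(i + 1) % self.k])

    def train(self, i: int) -> list[str]:
        excluded = set(self.test(i)) | set(self.validation(i))
        return [s for fold in self.test_sets for s in fold if s not in excluded]


def curate(
    specimens: pd.DataFrame,
    assignments: pd.DataFrame,
    features: pd.DataFrame,
    min_specimens_per_species: int = 5,
) -> CuratedDataset:
    """Merge weights + assignments + features and apply the exclusion rules."""
    weights = specimens.set_index("specimen_id")["measured_mass_mg"]
    asg = assignments.set_index("specimen_id")
    log: list[dict] = []
    kept: list[dict] = []

    surviving = []
    for sid in specimens["specimen_id"]:
        if sid not in asg.index or asg.loc[sid, "status"] != "assigned":
            log.append({"specimen_id": sid, "reason": "unassigned"})
        elif weights.loc[sid] <= 0:
            log.append({"specimen_id": sid, "reason": "below_detection"})
        else:
            surviving.append(sid)

    counts = asg.loc[surviving, "species"].value_counts()
    rare = set(counts[counts < min_specimens_per_species].index)
    clean_by_specimen = (
        features[~features["nontarget_flag"].astype(bool)].groupby("specimen_id").size()
        if len(features)
        else pd.Series(dtype=int)
    )
    for sid in surviving:
        if asg.loc[sid, "species"] in rare:
            log.append({"specimen_id": sid, "reason": "rare_species"})
        elif clean_by_specimen.get(sid, 0) == 0:
            log.append({"specimen_id": sid, "reason": "no_clean_frames"})
        else:
            kept.append(
                {
                    "specimen_id": sid,
                    "order": asg.loc[sid, "order"],
                    "family": asg.loc[sid, "family"],
                    "genus": asg.loc[sid, "genus"],
                    "species": asg.loc[sid, "species"],
                    "mass_mg": float(weights.loc[sid]),
                }
            )
    if not kept:
        raise EmptyDatasetError("curation removed every specimen")
    spdf = pd.DataFrame(kept)
    logdf = pd.DataFrame(log, columns=["specimen_id", "reason"])
    feats = features[features["specimen_id"].isin(spdf["specimen_id"])].reset_index(drop=True)
    return CuratedDataset(specimens=spdf, features=feats, exclusion_log=logdf)


def make_folds(dataset: CuratedDataset, k: int = 5, seed: int = 0) -> FoldSplit:
    """Species-stratified k-fold over specimens (the grouping unit)."""
    sp = dataset.specimens
    counts = sp["species"].value_counts()
    too_few = counts[counts < k]
    if len(too_few):
        raise InvalidDatasetError(
            f"species with fewer than k={k} specimens cannot be stratified: {dict(too_few)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = sp["specimen_id"].to_numpy()
    test_sets = [sorted(ids[test_idx]) for _, test_idx in skf.split(ids, sp["species"])]
    return FoldSplit(k=k, seed=seed, test_sets=test_sets)


def compute_global_max_dim(dataset: CuratedDataset) -> int:
    """G = max over clean frames of max(height, width), fixed in the manifest.

    Train and inference must share G so the global-aspect-ratio resize maps
    physical size to the same pixel scale everywhere.
    """
    clean = dataset.clean_frames()
    if clean.empty:
        raise EmptyDatasetError("no clean frames to compute the global max dimension from")
    return int(max(clean["height"].max(), clean["width"].max()))


def manifest_dict(dataset: CuratedDataset, folds: FoldSplit) -> dict:
    """dataset_manifest.json content."""
    fold_of = {sid: i for i, fold in enumerate(folds.test_sets) for sid in fold}
    return {
        "n_specimens": int(len(dataset.specimens)),
        "species": dataset.species,
        "global_max_dim": compute_global_max_dim(dataset),
        "k": folds.k,
        "seed": folds.seed,
        "fold_of_specimen": fold_of,
        "specimens": dataset.specimens.to_dict(orient="records"),
        "exclusion_log": dataset.exclusion_log.to_dict(orient="records"),
    }


def write_manifest(dataset: CuratedDataset, folds: FoldSplit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest_dict(dataset, folds), indent=1))
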