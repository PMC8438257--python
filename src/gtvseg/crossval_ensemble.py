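"""k-fold partition schemes, out-of-fold prediction, and six-way mask voting.

Every case in the cohort receives six binary predictions: three fold
schemes (two distinct 3-fold partitions and one 9-fold partition) times two
architectures (2D and 3D U-Net).  Within a scheme, the cohort is split into
k folds; for each fold a model is trained on the other k-1 folds (with
augmentation) and predicts the held-out fold, so no case is ever predicted
by a model that saw it during training.  The six binary masks are summed
voxelwise (votes 0..6) and thresholded: a voxel is tumor in the final mask
iff at least ``vote_threshold`` (default 3) members voted for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import Case, Mask
from .preprocess import AugmentationGrid, apply_augmentation, enumerate_augmentations
from .unet import UNetConfig, binarize, predict_case, train_model

__all__ = [
    "FoldScheme",
    "EnsembleResult",
    "SchemeRun",
    "make_fold_scheme",
    "run_scheme",
    "model_average",
    "run_full_pipeline",
    "audit_leakage",
]

SCHEME_IDS = ("threefold_A", "threefold_B", "ninefold")
ARCHS = ("unet2d", "unet3d")


@dataclass(frozen=True)
class FoldScheme:
    """A partition of case ids into k folds (sizes differing by at most 1)."""

    scheme_id: str
    k: int
    assignment: Mapping[str, int]  # case_id -> fold index in [0, k)
    rng_seed: int

    def fold_members(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        return [len(self.fold_members(f)) for f in range(self.k)]


def make_fold_scheme(
    case_ids: Sequence[str], k: int, seed: int, scheme_id: str = "scheme"
) -> FoldScheme:
    """Seeded shuffle followed by round-robin assignment to k folds."""
    n = len(case_ids)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if len(set(case_ids)) != n:
        raise ValueError("duplicate case ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {case_ids[int(idx)]: pos % k for pos, idx in enumerate(order)}
    return FoldScheme(scheme_id=scheme_id, k=k, assignment=assignment, rng_seed=seed)


@dataclass
class SchemeRun:
    """Out-of-fold predictions of one (scheme, architecture) pair.

    ``train_ledger`` records, per fold, which cases trained the model and
    which it predicted — the raw material for the leakage audit.
    """

    scheme: FoldScheme
    arch: str
    predictions: dict[str, Mask]
    train_ledger: list[dict]
    histories: list = field(default_factory=list)


def _augmented_pool(cases: Sequence[Case], grid: AugmentationGrid) -> list[Case]:
    transforms = enumerate_augmentations(grid)
    return [apply_augmentation(c, t) for c in cases for t in transforms]


def run_scheme(
    scheme: FoldScheme,
    arch: str,
    cohort: Sequence[Case],
    config: UNetConfig,
    augmentation: AugmentationGrid = AugmentationGrid(),
    binarize_threshold: float = 0.5,
    val_fraction: float = 0.25,
    model_sink=None,
) -> SchemeRun:
    """Train k models and collect one out-of-fold prediction per case."""
    if arch not in ARCHS:
        raise ValueError(f"arch must be one of {ARCHS}")
    by_id = {c.case_id: c for c in cohort}
    if set(by_id) != set(scheme.assignment):
        raise ValueError("scheme assignment does not match cohort case ids")
    for c in cohort:
        if c.mask is None:
            raise ValueError(f"case {c.case_id!r} is unlabeled; every case needs a mask")

    dims = 2 if arch == "unet2d" else 3
    predictions: dict[str, Mask] = {}
    ledger: list[dict] = []
    histories = []
    for fold in range(scheme.k):
        test_ids = scheme.fold_members(fold)
        train_ids = [cid for cid in by_id if scheme.assignment[cid] != fold]
        train_cases = _augmented_pool([by_id[cid] for cid in train_ids], augmentation)
        tag = sum(ord(ch) for ch in f"{scheme.scheme_id}/{arch}")  # stable across processes
        fold_seed = (config.rng_seed * 1000 + fold * 7 + tag) % (2**31)
        fold_cfg = UNetConfig(**{**config.__dict__, "dims": dims, "rng_seed": fold_seed})
        try:
            model = train_model(fold_cfg, train_cases, val_fraction=val_fraction)
        except Exception as exc:
            raise RuntimeError(
                f"{scheme.scheme_id}/{arch}: training failed in fold {fold}: {exc}"
            ) from exc
        if model_sink is not None:
            model_sink(scheme.scheme_id, arch, fold, model)
        for cid in test_ids:
            case = by_id[cid]
            prob = predict_case(model, case)
            predictions[cid] = binarize(prob, case.volume.spacing, binarize_threshold)
        ledger.append({"fold": fold, "train_ids": sorted(train_ids), "test_ids": sorted(test_ids)})
        histories.append(model.history)
    return SchemeRun(scheme=scheme, arch=arch, predictions=predictions,
                     train_ledger=ledger, histories=histories)


@dataclass
class EnsembleResult:
    """Six member masks, their voxelwise vote sum and the fused final mask."""

    case_id: str
    members: dict[str, Mask]  # keys like "threefold_A/unet2d"
    vote_sum: np.ndarray  # values in 0..6
    final_mask: Mask
    vote_threshold: int = 3


def model_average(
    members: Mapping[str, Mask] | Sequence[Mask],
    vote_threshold: int = 3,
    case_id: str = "",
) -> EnsembleResult:
    """Sum exactly six geometry-matched binary masks and threshold the votes.

    A voxel is tumor iff its vote count >= ``vote_threshold`` (>= convention,
    so a 3-of-6 tie counts as tumor).
    """
    if isinstance(members, Mapping):
        member_map = dict(members)
    else:
        member_map = {f"member_{i}": m for i, m in enumerate(members)}
    if len(member_map) != 6:
        raise ValueError(f"model averaging requires exactly 6 members, got {len(member_map)}")
    masks = list(member_map.values())
    shape = masks[0].shape
    spacing = masks[0].spacing
    for m in masks[1:]:
        if m.shape != shape or m.spacing != spacing:
            raise ValueError("member masks disagree in geometry")
    vote_sum = np.sum([m.voxels.astype(np.int16) for m in masks], axis=0)
    final = Mask(voxels=(vote_sum >= vote_threshold).astype(np.uint8), spacing=spacing)
    return EnsembleResult(
        case_id=case_id, members=member_map, vote_sum=vote_sum,
        final_mask=final, vote_threshold=vote_threshold,
    )


def run_full_pipeline(
    cohort: Sequence[Case],
    config2d: UNetConfig,
    config3d: UNetConfig,
    scheme_seeds: tuple[int, int, int] = (11, 23, 37),
    augmentation: AugmentationGrid = AugmentationGrid(),
    vote_threshold: int = 3,
    val_fraction: float = 0.25,
    model_sink=None,
) -> tuple[dict[str, EnsembleResult], list[SchemeRun]]:
    """Run all six (scheme x architecture) members and fuse per case.

    Returns the per-case ensemble results and the six scheme runs (with
    their fold ledgers), preserving every member mask for the single-model
    versus model-average comparison.
    """
    ids = [c.case_id for c in cohort]
    seed_a, seed_b, seed_9 = scheme_seeds
    scheme_a = make_fold_scheme(ids, 3, seed_a, "threefold_A")
    scheme_b = make_fold_scheme(ids, 3, seed_b, "threefold_B")
    if len(ids) > 3 and scheme_a.assignment == scheme_b.assignment:
        # the two 3-fold schemes must be distinct partitions; nudge seed B
        scheme_b = make_fold_scheme(ids, 3, seed_b + 1, "threefold_B")
    scheme_9 = make_fold_scheme(ids, min(9, len(ids)), seed_9, "ninefold")

    runs: list[SchemeRun] = []
    for scheme in (scheme_a, scheme_b, scheme_9):
        for arch, cfg in (("unet2d", config2d), ("unet3d", config3d)):
            runs.append(
                run_scheme(scheme, arch, cohort, cfg, augmentation=augmentation,
                           val_fraction=val_fraction, model_sink=model_sink)
            )

    results: dict[str, EnsembleResult] = {}
    for cid in ids:
        members = {f"{r.scheme.scheme_id}/{r.arch}": r.predictions[cid] for r in runs}
        results[cid] = model_average(members, vote_threshold=vote_threshold, case_id=cid)
    return results, runs


def audit_leakage(runs: Sequence[SchemeRun]) -> list[str]:
    """Structural leakage check over fold ledgers.

    Returns the list of violations (empty when no case was ever predicted
    by a model whose training set contained it, and every case was
    predicted exactly once per run).
    """
    problems: list[str] = []
    for run in runs:
        seen: set[str] = set()
        for entry in run.train_ledger:
            overlap = set(entry["train_ids"]) & set(entry["test_ids"])
            if overlap:
                problems.append(
                    f"{run.scheme.scheme_id}/{run.arch} fold {entry['fold']}: "
                    f"cases in both train and test: {sorted(overlap)}"
                )
            dupes = seen & set(entry["test_ids"])
            if dupes:
                problems.append(
                    f"{run.scheme.scheme_id}/{run.arch}: cases predicted twice: {sorted(dupes)}"
                )
            seen |= set(entry["test_ids"])
        if seen != set(run.scheme.assignment):
            problems.append(
                f"{run.scheme.scheme_id}/{run.arch}: not every case predicted"
            )
    return problems
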