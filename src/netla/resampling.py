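"""Repeated train/test resampling with optional family grouping.

Two schemes are provided. RS1 assigns subjects to the train or test side
uniformly at random, ignoring family structure — the common but leaky
practice when cohorts contain twins and siblings. RS2 assigns whole families
to one side only, so no family ever straddles the split; the test set is
grown family by family until it first reaches the target size. Nested
five-fold inner cross-validation folds (for hyperparameter selection) are
drawn inside each repetition's training set and, under RS2, are also
family-grouped so that hyperparameter selection cannot leak either.

Repetition seeds are derived from the master seed by a counter scheme
(``default_rng([seed, repetition])``) so any single repetition can be
re-drawn in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitPlan", "make_splits", "make_inner_folds", "splits_to_frame"]

RS1 = "RS1"
RS2 = "RS2"


@dataclass(frozen=True)
class SplitPlan:
    """One repetition's train/test membership plus inner CV folds.

    Indices are integer row positions into the dataset. ``inner_folds`` is a
    list of ``(inner_train, inner_validation)`` index pairs partitioning the
    training set.
    """

    repetition: int
    scheme: str
    train: np.ndarray
    test: np.ndarray
    inner_folds: tuple

    def validate(self, family_ids=None) -> None:
        train, test = set(self.train.tolist()), set(self.test.tolist())
        if train & test:
            raise AssertionError("train and test overlap")
        covered = np.concatenate([np.concatenate([v for _, v in self.inner_folds])])
        if sorted(covered.tolist()) != sorted(self.train.tolist()):
            raise AssertionError("inner validation folds do not partition train")
        if self.scheme == RS2 and family_ids is not None:
            if set(family_ids[self.train]) & set(family_ids[self.test]):
                raise AssertionError("family straddles the RS2 split")


def _rep_rng(seed, repetition: int) -> np.random.Generator:
    key = [int(seed)] if np.ndim(seed) == 0 else [int(s) for s in seed]
    return np.random.default_rng(key + [int(repetition)])


def make_inner_folds(
    train_idx: np.ndarray,
    family_ids: np.ndarray | None,
    k: int = 5,
    grouped: bool = False,
    rng: np.random.Generator | None = None,
    seed=None,
) -> tuple:
    """Partition ``train_idx`` into ``k`` (inner-train, validation) folds.

    With ``grouped=True`` all members of a family land in the same
    validation fold; families are shuffled and assigned to the currently
    smallest fold so fold sizes stay balanced.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    train_idx = np.asarray(train_idx)
    if train_idx.size < k:
        raise ValueError(f"cannot make {k} folds from {train_idx.size} subjects")
    if rng is None:
        rng = np.random.default_rng(seed)

    if grouped:
        if family_ids is None:
            raise ValueError("grouped folds require family ids")
        fams = family_ids[train_idx]
        uniq = np.unique(fams)
        if uniq.size < k:
            raise ValueError(
                f"only {uniq.size} families in the training set; need >= {k}"
            )
        order = rng.permutation(uniq)
        fold_of_fam = {}
        fold_sizes = np.zeros(k, dtype=np.int64)
        fam_size = {f: int(np.sum(fams == f)) for f in uniq}
        for fam in order:
            target = int(np.argmin(fold_sizes))
            fold_of_fam[fam] = target
            fold_sizes[target] += fam_size[fam]
        fold_of_subject = np.array([fold_of_fam[f] for f in fams])
    else:
        perm = rng.permutation(train_idx.size)
        fold_of_subject = np.empty(train_idx.size, dtype=np.int64)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of_subject[chunk] = f

    folds = []
    for f in range(k):
        val = train_idx[fold_of_subject == f]
        tr = train_idx[fold_of_subject != f]
        folds.append((tr, val))
    return tuple(folds)


def make_splits(
    dataset,
    scheme: str = RS2,
    test_frac: float = 0.2,
    n_repetitions: int = 1000,
    seed=0,
    k_inner: int = 5,
) -> list[SplitPlan]:
    """Draw ``n_repetitions`` independent train/test plans.

    RS1 samples subjects uniformly without replacement (test size exactly
    ``round(test_frac * n)``); RS2 accumulates shuffled whole families into
    the test set until it first reaches that target, overshooting by at most
    one family.
    """
    if scheme not in (RS1, RS2):
        raise ValueError(f"unknown scheme '{scheme}'")
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    n = dataset.n_subjects
    if n == 0:
        raise ValueError("dataset is empty")
    family_ids = dataset.family_ids
    n_test = max(1, int(round(test_frac * n)))
    if n_test >= n:
        raise ValueError("test fraction leaves no training subjects")

    if scheme == RS2:
        uniq, counts = np.unique(family_ids, return_counts=True)
        if counts.max() > n_test:
            raise ValueError(
                f"largest family ({counts.max()} members) exceeds the test-set "
                f"target ({n_test}); lower test_frac or split families"
            )

    uniq_fams = np.unique(family_ids)
    members = {f: np.nonzero(family_ids == f)[0] for f in uniq_fams}

    plans = []
    for rep in range(n_repetitions):
        rng = _rep_rng(seed, rep)
        if scheme == RS1:
            perm = rng.permutation(n)
            test = np.sort(perm[:n_test])
            train = np.sort(perm[n_test:])
        else:
            fam_order = rng.permutation(uniq_fams)
            test_parts, size = [], 0
            it = iter(fam_order)
            while size < n_test:
                fam = next(it)
                test_parts.append(members[fam])
                size += members[fam].size
            test = np.sort(np.concatenate(test_parts))
            train = np.sort(np.setdiff1d(np.arange(n), test, assume_unique=True))
        folds = make_inner_folds(
            train,
            family_ids,
            k=k_inner,
            grouped=(scheme == RS2),
            rng=rng,
        )
        plans.append(SplitPlan(rep, scheme, train, test, folds))
    return plans


def splits_to_frame(plans: list[SplitPlan], subject_ids: np.ndarray) -> pd.DataFrame:
    """Audit export: one row per (repetition, subject) with its role."""
    rows = []
    for plan in plans:
        for idx in plan.train:
            rows.append((plan.repetition, subject_ids[idx], "train"))
        for idx in plan.test:
            rows.append((plan.repetition, subject_ids[idx], "test"))
    return pd.DataFrame(rows, columns=["repetition", "subject_id", "role"])
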