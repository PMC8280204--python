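from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from perifw import default_gradient_table
from perifw.cnn import CnnClassifier, ModelConfig, balance_patches
from perifw.experiment import (ExperimentConfig, subject_patches,
                               subject_scalar_maps)
from perifw.synthetic import generate_cohort, simulate_dwi


@pytest.fixture(scope="session")
def gtab():
    """The reference acquisition: 3 b=0 volumes + 30 directions at b=1000."""
    return default_gradient_table()


def _collect_patchsets(n_gbm, n_met, cohort_seed, snr, gtab, augment):
    """Simulate DWI, fit FW-VF, and sample patches for each phantom subject."""
    out = []
    for subject in generate_cohort(n_gbm, n_met, seed=cohort_seed):
        masks = {"brain": subject.brain, "tumor": subject.tumor,
                 "edema": subject.edema}
        dwi = simulate_dwi(subject, gtab=gtab, snr=snr,
                           seed=subject.params.seed + 1)
        smaps = subject_scalar_maps(dwi, masks, {"FW-VF"})
        ps = subject_patches(smaps, masks, "FW-VF", subject.subject_id,
                             subject.label, seed=subject.params.seed + 2,
                             n_aug=1 if augment else 0)
        out.append((subject.subject_id, subject.label, ps))
    return out


@pytest.fixture(scope="session")
def trained_cohort(gtab):
    """The benchmark condition: 20+20 training and 5+5 held-out phantom
    subjects with the default class texture contrast (edema mean FW-VF 0.55
    vs 0.80), full simulate-and-fit chain at SNR 30, one CNN trained on the
    balanced, shift-augmented FW-VF training patches.

    Built once per session; shared by the classifier-property and
    acceptance tests.
    """
    from perifw.cnn import predict_patch_probs

    train = _collect_patchsets(20, 20, cohort_seed=11, snr=30.0,
                               gtab=gtab, augment=True)
    test = _collect_patchsets(5, 5, cohort_seed=12, snr=30.0,
                              gtab=gtab, augment=False)
    pooled = None
    for _, _, ps in train:
        pooled = ps if pooled is None else pooled.extend(ps)
    pooled = balance_patches(pooled, seed=0)
    clf = CnnClassifier(ModelConfig(epochs=25, seed=0))
    clf.fit(pooled)
    return {"train": train, "test": test, "pooled_train": pooled, "clf": clf}
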