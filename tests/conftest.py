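import numpy as np
import pytest

from dilinet import (ModelConfig, TrainConfig, evaluate_model, fit, fit_baseline,
                     split_dataset)
from dilinet.featurize import fold_to_input
from dilinet.synthetic import SynthConfig, generate_fingerprint_dataset, oracle_scores

RECOVERY_SEED = 0  # fixed up front for the end-to-end recovery study


@pytest.fixture(scope="session")
def recovery_study():
    """End-to-end run at the study conditions: n=2000 fingerprint-mode data
    with 20 informative bits and label-flip probability 0.1, one fixed seed.

    Shared session-wide because training plus three baselines is the most
    expensive computation in the suite.
    """
    cfg = SynthConfig(n=2000, n_informative_bits=20, label_flip_prob=0.1,
                      seed=RECOVERY_SEED)
    x_fp, y, truth = generate_fingerprint_dataset(cfg)
    x_net = fold_to_input(x_fp)
    split = split_dataset(len(y), RECOVERY_SEED)
    model, history = fit(x_net, y, split, ModelConfig(), TrainConfig(seed=RECOVERY_SEED))
    model_metrics = evaluate_model(model, x_net[split.test], y[split.test])
    dev = np.concatenate([split.train, split.val])
    baseline_metrics = {}
    for kind in ("RF", "SVM", "LR"):
        clf = fit_baseline(kind, x_fp[dev], y[dev], seed=RECOVERY_SEED)
        baseline_metrics[kind] = evaluate_model(clf, x_fp[split.test], y[split.test])
    return {
        "config": cfg,
        "x_fp": x_fp,
        "x_net": x_net,
        "y": y,
        "truth": truth,
        "split": split,
        "model": model,
        "history": history,
        "model_metrics": model_metrics,
        "baseline_metrics": baseline_metrics,
        "oracle_test_scores": oracle_scores(x_fp[split.test], truth["informative_bits"]),
    }
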