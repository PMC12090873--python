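import numpy as np
import pytest

from ringseg.config import RunConfig
from ringseg.experiments import make_dataset, run_end_to_end, tiny_config
from ringseg.semantic import SemanticOutput, derive_semantic_targets
from ringseg.synthetic import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def simple_sample():
    """One deterministic 5-ring sample with wedging."""
    spec = SyntheticSpec(seed=5, n_rings=5, wedging_prob=0.5,
                         mean_ring_width=15.0)
    return generate_sample(spec)


@pytest.fixture(scope="session")
def concentric_sample():
    """Zero-jitter concentric rings: fully analytic geometry."""
    spec = SyntheticSpec(seed=2, n_rings=4, wedging_prob=0.0,
                         width_jitter=0.0, mean_ring_width=20.0,
                         pith_radius=16.0, texture_noise_sd=0.0)
    return generate_sample(spec)


def gt_semantic(mask, factor=4):
    """Idealized semantic output derived from the ground-truth mask."""
    targets = derive_semantic_targets(mask, factor=factor)
    logits = np.stack([
        np.where(targets[k], 8.0, -8.0)
        for k in ("pith", "background", "ring", "boundary")
    ]).astype(np.float32)
    return SemanticOutput(logits=logits)


@pytest.fixture(scope="session")
def trained_models(tmp_path_factory):
    """Tiny models trained once per session on the reference study:
    40 synthetic training images, 10 held-out; 50 segmentation epochs,
    30 regression epochs with K=3 iterative unrolling, plus the
    uncertainty (Laplace NLL) regression variant on the same split."""
    work = tmp_path_factory.mktemp("train")
    l1 = run_end_to_end(seed=1, n_train=40, n_test=10, seg_epochs=50,
                        reg_epochs=30, work_dir=work / "l1")
    nll = run_end_to_end(seed=1, seg_epochs=50, reg_epochs=30,
                         with_uncertainty=True, work_dir=work / "nll",
                         seg_model=l1["seg_model"],
                         train_set=l1["train_set"], test_set=l1["test_set"])
    return {"l1": l1, "nll": nll, "config": tiny_config()}
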