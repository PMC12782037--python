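import numpy as np
import pytest

from megamorph import synthgen as sg


@pytest.fixture(scope="session")
def taxonomy14():
    return sg.generate_taxonomy(14, 13, 7, 3, seed=1)


@pytest.fixture(scope="session")
def taxonomy8():
    return sg.generate_taxonomy(8, 7, 4, 3, seed=1)


def random_blob_mask(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """Union of 1-3 random rotated ellipses, guaranteed non-empty."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    mask = np.zeros((size, size), bool)
    for _ in range(int(rng.integers(1, 4))):
        cy, cx = rng.uniform(size * 0.3, size * 0.7, 2)
        a, b = rng.uniform(3, size * 0.3, 2)
        th = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        mask[size // 2, size // 2] = True
    return mask


@pytest.fixture(scope="session")
def failure_injection_run(taxonomy8):
    """2,000 specimens with the study-echoing injected failure rates."""
    allom = sg.default_allometry(taxonomy8, 3)
    lengths = sg.default_lengths(taxonomy8)
    specimens = sg.generate_specimens(taxonomy8, 250, allom, lengths, seed=11)
    records, ledger = sg.generate_otu_table(
        specimens,
        taxonomy8,
        sg.ReadParams(),
        sg.FailureRates(p_noreads=0.072, p_mismatch=0.034, p_nospecies=0.031, p_repeat=0.1),
        seed=11,
    )
    return specimens, records, ledger, taxonomy8


@pytest.fixture(scope="session")
def mini_pipeline(tmp_path_factory):
    """A small but complete pipeline run shared by orchestration tests."""
    from megamorph.pipeline import default_config, run_pipeline

    cfg = default_config()
    cfg["seed"] = 3
    cfg["synthgen"].update(
        n_species=4,
        n_genera=4,
        n_families=3,
        n_orders=2,
        n_per_species=6,
        n_frames=6,
        image_height=96,
        image_width=96,
        px_per_mm=6.0,
        write_images=True,
        p_noreads=0.0,
        p_mismatch=0.0,
        p_nospecies=0.0,
    )
    cfg["build"].update(k=3, min_specimens_per_species=3)
    cfg["models"].update(input_size=32, channels=[8, 16])
    cfg["models"]["classify"].update(epochs=2)
    cfg["models"]["regress"].update(epochs=2)
    cfg["models"]["pretrained"].update(epochs=1)
    out = tmp_path_factory.mktemp("mini_run")
    ctx = run_pipeline(cfg, out_root=out)
    return cfg, out, ctx
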