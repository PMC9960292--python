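import numpy as np
import pandas as pd
import pytest

import mbopls as m


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default design (seed 1)."""
    cfg = m.GeneratorConfig(seed=1)
    design, gt, neg, pos, plate = m.generate_dataset(cfg)
    return {"config": cfg, "design": design, "gt": gt,
            "neg": neg, "pos": pos, "plate": plate}


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    """Filtered blocks + fitted consensus model + loadings for the default study."""
    d = default_dataset
    activity = m.summarize_activity(d["plate"])
    y = activity.set_index("sample_id").loc[
        d["design"]["sample_id"], "inhibition_percent"].to_numpy()
    neg_f, pos_f, prov = m.assemble_blocks(d["neg"], d["pos"], d["design"])
    model = m.fit_consensus_opls(
        [neg_f, pos_f], y, n_ortho=1, block_names=["neg", "pos"],
        ion_ids=[neg_f.ion_ids, pos_f.ion_ids])
    loadings = m.back_project_loadings(model, [neg_f, pos_f])
    return {"y": y, "neg_f": neg_f, "pos_f": pos_f, "provenance": prov,
            "model": model, "loadings": loadings, **d}


def run_scenario(seed, **config_overrides):
    """Generate -> assay -> filter -> fit for one seed; returns a result dict."""
    cfg = m.GeneratorConfig(seed=seed, **config_overrides)
    design, gt, neg, pos, plate = m.generate_dataset(cfg)
    activity = m.summarize_activity(plate)
    y = activity.set_index("sample_id").loc[
        design["sample_id"], "inhibition_percent"].to_numpy()
    neg_f, pos_f, _ = m.assemble_blocks(neg, pos, design)
    model = m.fit_consensus_opls([neg_f, pos_f], y, n_ortho=1,
                                 block_names=["neg", "pos"],
                                 ion_ids=[neg_f.ion_ids, pos_f.ion_ids])
    loadings = m.back_project_loadings(model, [neg_f, pos_f])
    return {"config": cfg, "design": design, "gt": gt, "y": y,
            "neg_f": neg_f, "pos_f": pos_f, "model": model, "loadings": loadings}


def tiny_block(intensities, rts, mode="neg", sample_ids=None):
    """Hand-built FeatureBlock from a 2-D array and per-ion retention times."""
    X = np.asarray(intensities, dtype=float)
    n, p = X.shape
    ids = [f"{mode}_i{j}" for j in range(p)]
    samples = sample_ids or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(X, index=pd.Index(samples, name="sample_id"), columns=ids)
    ions = pd.DataFrame({"mz": np.linspace(100, 200, p), "rt": rts},
                        index=pd.Index(ids, name="ion_id"))
    return m.FeatureBlock(df, ions, mode)
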