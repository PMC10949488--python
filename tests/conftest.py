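import numpy as np
import pandas as pd
import pytest

from phagescore.features import empty_feature_table
from phagescore.mockmeta import CompositionSpec
from phagescore.simulate import ToolErrorProfile, default_profiles, make_benchmark_bundle
from phagescore.features import TOOLS


def make_row(**features) -> dict:
    """A single feature-table row with all tool signals absent by default."""
    row = {
        "length_bp": 5000,
        "vs2_score": np.nan,
        "vs2_hallmark": np.nan,
        "vs2_group": None,
        "vb_quality": "none",
        "vb_vog_genes": np.nan,
        "vb_total_genes": np.nan,
        "vs_category": np.nan,
        "dvf_score": np.nan,
        "dvf_pvalue": np.nan,
        "cv_viral_genes": np.nan,
        "cv_host_genes": np.nan,
        "cv_completeness": np.nan,
        "cv_quality": None,
        "kj_classified": False,
        "kj_taxon_path": None,
        "kj_is_viral": None,
    }
    row.update(features)
    return row


def make_table(rows: dict) -> pd.DataFrame:
    """Feature table from {seq_id: feature-overrides}."""
    table = empty_feature_table(rows.keys())
    for sid, feats in rows.items():
        for name, value in feats.items():
            table.at[sid, name] = value
    return table


@pytest.fixture
def feature_row():
    return make_row


@pytest.fixture
def feature_table():
    return make_table


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Small benchmark bundle with perfect tools: 2 replicates x 200 seqs."""
    profiles = default_profiles(
        **{t: ToolErrorProfile(1.0, 1.0, 0.0, 0.0) for t in TOOLS}
    )
    spec = CompositionSpec(total_sequences=200, n_replicates=2)
    outdir = tmp_path_factory.mktemp("noiseless_bundle")
    return make_benchmark_bundle(spec, profiles, seed=42, outdir=outdir)


def load_bundle_tables(bundle):
    """Parse a bundle back through the tool-output readers."""
    from phagescore.features import merge_features, read_labels, read_tool_output

    features_per_rep, labels_per_rep = [], []
    for rep in bundle["replicates"]:
        files = rep["files"]
        frags = []
        for tool in TOOLS:
            kwargs = (
                {"annotation_path": files["vibrant_annotations"]}
                if tool == "vibrant"
                else {}
            )
            frags.extend(read_tool_output(files[tool], tool, **kwargs))
        mock = bundle["mocks"][rep["replicate"]]
        lengths = {r.id: len(r.seq) for r in mock.records}
        features_per_rep.append(merge_features(frags, lengths))
        labels_per_rep.append(read_labels(files["labels"]))
    return features_per_rep, labels_per_rep
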