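"""Bundled reference datasets.

These encode the published summary tables of the study cohort the pipeline
was designed around: per-patient clinical metadata, the two- and three-spot
cluster memberships, the published differential-spot group means, and the
published pair of linear classification functions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as tabio
from .cluster import ClusterAssignment, assignment_from_mapping
from .discriminant import FIXTURE, DiscriminantModel

_DATA = resources.files(__package__) / "data"


def load_reference_clinical() -> pd.DataFrame:
    """Clinical metadata of the 24-patient reference cohort."""
    with resources.as_file(_DATA / "reference_clinical.tsv") as path:
        return tabio.read_clinical_table(path)


def load_reference_clusters() -> pd.DataFrame:
    """Two-spot and three-spot cluster membership of the reference cohort."""
    with resources.as_file(_DATA / "reference_clusters.tsv") as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return df


def reference_assignment(stratification: str) -> ClusterAssignment:
    """Cluster assignment fixture; ``stratification`` is 'two_spot' or 'three_spot'."""
    df = load_reference_clusters()
    col = {"two_spot": "cluster_two_spot", "three_spot": "cluster_three_spot"}[stratification]
    return assignment_from_mapping(dict(zip(df["patient_id"], df[col])))


def load_reference_differential_means() -> pd.DataFrame:
    """Published per-cluster mean +/- SD %Vol of the differential spots."""
    with resources.as_file(_DATA / "reference_differential_means.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype={"spot_id": str})


def reference_discriminant_model() -> DiscriminantModel:
    """The published two-function linear discriminant over spots 288/289."""
    with resources.as_file(_DATA / "reference_discriminant.tsv") as path:
        df = pd.read_csv(path, sep="\t", dtype={"group": str, "term": str})
    return DiscriminantModel.from_frame(df, provenance=FIXTURE)
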