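"""Packaged text fixtures.

* ``study_metadata.tsv`` — the seven-study design table (accessions,
  platforms and arm sizes) used for the sample accounting.
* ``interactions46.synthetic.tsv`` — a synthetic 46-node confidence-
  weighted edge list over the transporter gene symbols, with planted
  substrate-class communities (amino-acid, vitamin, ion/microelement and
  a lipid/carbohydrate remainder) mimicking the shape of a medium-
  confidence protein-interaction network.  Intra-community edges score
  0.6-0.95 and the sparse inter-community bridges 0.41-0.5, so community
  recovery by Markov clustering is a genuine clustering task (the graph
  stays connected after the 0.4 filter).
"""

from __future__ import annotations

from importlib.resources import as_file, files

import pandas as pd

from .tabular_io import StudyMeta, read_edge_list, read_study_metadata

__all__ = [
    "study_metadata",
    "interaction_fixture",
    "interaction_fixture_communities",
]


def _data(name: str):
    return files("placscreen").joinpath("data", name)


def study_metadata() -> list[StudyMeta]:
    """The packaged seven-study metadata table."""
    with as_file(_data("study_metadata.tsv")) as path:
        return read_study_metadata(path)


def interaction_fixture() -> pd.DataFrame:
    """Edge list of the synthetic 46-node interaction network."""
    with as_file(_data("interactions46.synthetic.tsv")) as path:
        return read_edge_list(path)


def interaction_fixture_communities() -> dict[str, list[str]]:
    """Planted community membership of the 46-node fixture."""
    with as_file(_data("interactions46.synthetic.communities.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return {name: sorted(sub["node"]) for name, sub in df.groupby("community")}
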