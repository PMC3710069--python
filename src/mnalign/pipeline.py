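"""End-to-end alignment pipeline.

Wires the stages together: transition models -> SMRW correspondence
scores -> pairwise alignment probabilities -> intra-network consistency
transform -> network homology weights -> cross-network consistency
transform -> greedy maximum-expected-accuracy construction.  The two
transforms can be skipped individually for ablation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aligner import Alignment, greedy_mea_align
from .consistency import cross_transform, homology_weight, intra_transform
from .netio import Network, RunConfig, SimilarityScores
from .smrw import (
    ProbMatrix,
    TransitionModel,
    alignment_probabilities,
    build_transition_model,
    correspondence_scores,
)


@dataclass
class PipelineResult:
    alignment: Alignment
    raw: dict[frozenset, ProbMatrix]
    intra: dict[frozenset, ProbMatrix]
    cross: dict[frozenset, ProbMatrix]
    homology: dict[frozenset, float] = field(default_factory=dict)


def _pair_key(sim: SimilarityScores) -> frozenset:
    return frozenset((sim.net_a, sim.net_b))


def align_networks(
    networks: list[Network],
    similarities: dict[frozenset, SimilarityScores] | list[SimilarityScores],
    config: RunConfig | None = None,
    skip_intra: bool = False,
    skip_cross: bool = False,
) -> PipelineResult:
    """Run the full pipeline and return the alignment plus every
    intermediate probability matrix (for inspection and ablation)."""
    config = config or RunConfig()
    if isinstance(similarities, list):
        similarities = {_pair_key(s): s for s in similarities}
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    by_name = {n.name: n for n in networks}
    if len(by_name) != len(networks):
        raise ValueError("network names must be unique")
    expected = {
        frozenset((a.name, b.name))
        for i, a in enumerate(networks) for b in networks[i + 1:]
    }
    missing = expected - set(similarities)
    if missing:
        pair = sorted(sorted(p) for p in missing)[0]
        raise KeyError(f"missing similarity scores for pair {tuple(pair)}")

    tms: dict[str, TransitionModel] = {
        n.name: build_transition_model(n) for n in networks
    }

    raw: dict[frozenset, ProbMatrix] = {}
    for key in sorted(expected, key=sorted):
        sim = similarities[key]
        corr = correspondence_scores(tms[sim.net_a], tms[sim.net_b], sim)
        raw[key] = alignment_probabilities(corr)

    if skip_intra:
        intra = {
            k: ProbMatrix(p.net_a, p.net_b, p.nodes_a, p.nodes_b, p.mat,
                          p.index_a, p.index_b, stage="intra")
            for k, p in raw.items()
        }
    else:
        intra = {
            k: intra_transform(
                p, tms[p.net_a], tms[p.net_b], config.alpha, config.top_fraction
            )
            for k, p in raw.items()
        }

    homology: dict[frozenset, float] = {}
    cross: dict[frozenset, ProbMatrix] = {}
    if skip_cross:
        cross = {
            k: ProbMatrix(p.net_a, p.net_b, p.nodes_a, p.nodes_b, p.mat,
                          p.index_a, p.index_b, stage="cross")
            for k, p in intra.items()
        }
    else:
        stage = raw if config.homology_stage == "raw" else intra
        for k, p in stage.items():
            homology[k] = homology_weight(p, config.matching_normalizer).value
        for k in sorted(intra, key=sorted):
            a, b = sorted(k)
            cross[k] = cross_transform(intra, homology, a, b, config.top_fraction)

    alignment = greedy_mea_align(cross, config)
    return PipelineResult(alignment, raw, intra, cross, homology)
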