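"""End-to-end metric assembly: one comparison, every score.

:func:`compute_metrics` takes a reference labelling and a clustering,
plus either ready-made weights/tree or a labelled expression matrix to
estimate them from, and returns a :class:`MetricReport` with the
classical scores (RI, ARI, MI, NMI) and their hierarchy-weighted
counterparts (wRI, wPPV, wNPV, wMI, wNMI) side by side.  The report
records enough provenance (input sources, gene count, package version)
to recompute every number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .errors import SchemaError
from .partitions import PartitionLabels, build_contingency, pair_counts
from .structured_entropy import (
    ReferenceTree,
    entropy,
    mutual_information,
    nmi,
    weighted_nmi,
)
from .weight_estimation import (
    ExpressionMatrix,
    build_reference_tree,
    estimate_w0,
    estimate_w1,
    mean_profiles,
    top_variable_genes,
)
from .weighted_rand import (
    WeightMatrices,
    adjusted_rand_index,
    rand_index,
    weighted_predictive_values,
    weighted_rand_index,
)

__all__ = ["MetricReport", "compute_metrics"]

_METRIC_ORDER = ("RI", "ARI", "wRI", "wPPV", "wNPV", "MI", "NMI", "wMI", "wNMI")


@dataclass(frozen=True)
class MetricReport:
    """All scores for one clustering-vs-reference comparison.

    Metrics that need inputs that were not supplied (weights for the
    Rand family, a tree for the entropy family) are ``None``.
    """

    RI: float
    ARI: float
    MI: float
    NMI: float
    wRI: Optional[float] = None
    wPPV: Optional[float] = None
    wNPV: Optional[float] = None
    wMI: Optional[float] = None
    wNMI: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": {name: getattr(self, name) for name in _METRIC_ORDER},
            "provenance": dict(self.provenance),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)

    def format_row(self, precision: int = 3) -> dict:
        """Metric values rounded for display (full precision lives in
        the JSON output only)."""
        out = {}
        for name in _METRIC_ORDER:
            v = getattr(self, name)
            out[name] = "-" if v is None else f"{v:.{precision}f}"
        return out


def compute_metrics(
    ref: PartitionLabels,
    clust: PartitionLabels,
    weights: Optional[WeightMatrices] = None,
    tree: Optional[ReferenceTree] = None,
    expr: Optional[ExpressionMatrix] = None,
    n_top_genes: int = 1000,
    heterogeneity: str = "pairwise",
    linkage: str = "complete",
    metric: str = "euclidean",
    provenance: Optional[dict] = None,
) -> MetricReport:
    """Compute every available agreement metric for one comparison.

    Weights and tree may be supplied directly, estimated from ``expr``
    (a labelled expression matrix), or omitted — in which case only the
    classical metrics are reported.  Supplied objects always win over
    estimation.
    """
    prov = {
        "package_version": __version__,
        "weight_source": "supplied" if weights is not None else None,
        "tree_source": "supplied" if tree is not None else None,
        "n_top_genes": None,
    }
    if expr is not None and (weights is None or tree is None):
        mp = mean_profiles(expr, ref)
        genes = top_variable_genes(mp, k=n_top_genes)
        prov["n_top_genes"] = int(len(genes))
        if weights is None:
            weights = WeightMatrices(
                w1=estimate_w1(mp, genes),
                w0=estimate_w0(expr, ref, genes, method=heterogeneity),
                type_labels=ref.groups,
            )
            prov["weight_source"] = "estimated"
        if tree is None:
            tree = build_reference_tree(mp, genes, method=linkage, metric=metric)
            prov["tree_source"] = "estimated"
    if weights is None and tree is None and expr is None:
        raise SchemaError(
            "nothing to weight with: either supply weight matrices (W1/W0) "
            "and/or a reference tree, or supply a labelled expression matrix "
            "to estimate them from"
        )
    if provenance:
        prov.update(provenance)

    ct = build_contingency(ref, clust)
    pc = pair_counts(ct)
    out = dict(
        RI=rand_index(pc),
        ARI=adjusted_rand_index(ct),
        MI=mutual_information(ct),
        NMI=nmi(ref, clust),
    )
    if weights is not None:
        out["wRI"] = weighted_rand_index(ref, clust, weights)
        out["wPPV"], out["wNPV"] = weighted_predictive_values(ref, clust, weights)
    if tree is not None:
        out["wMI"], out["wNMI"] = weighted_nmi(ref, tree, clust)
    return MetricReport(provenance=prov, **out)
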