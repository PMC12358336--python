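"""Serialization of groups, weights, matrices, censuses and certificates.

Weights are exchanged as JSON with rational values rendered as strings
("3/2"), keyed by element enumeration index; matrices as CSV or
MatrixMarket coordinate text; censuses as CSV via pandas.  Primary
outputs written by the CLI embed (group, command, seed, version)
metadata so every file is self-describing.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from .arrangement import Census, Chamber
from .construction import DimensionCertificate
from .groups import GroupSpec
from .jacobian import ReducedWeight


def group_to_json(G: GroupSpec) -> str:
    return json.dumps({"factors": list(G.factors)})


def group_from_json(text: str) -> GroupSpec:
    return GroupSpec(tuple(json.loads(text)["factors"]))


def weight_to_dict(G: GroupSpec, rw: ReducedWeight) -> dict[str, dict[str, str]]:
    els = G.elements()
    return {
        "mu": {str(i): str(rw.mu[g]) for i, g in enumerate(els)},
        "nu": {str(i): str(rw.nu[g]) for i, g in enumerate(els)},
    }


def weight_from_dict(G: GroupSpec, d: Mapping[str, Mapping[str, str]]) -> ReducedWeight:
    els = G.elements()
    return ReducedWeight(
        mu={els[int(i)]: Fraction(v) for i, v in d["mu"].items()},
        nu={els[int(i)]: Fraction(v) for i, v in d["nu"].items()},
    )


def matrix_to_csv(M: np.ndarray, path: "str | Path") -> None:
    np.savetxt(path, np.asarray(M, dtype=np.int64), fmt="%d", delimiter=",")


def matrix_to_mtx(M: np.ndarray, path: "str | Path") -> None:
    mmwrite(str(path), coo_matrix(np.asarray(M, dtype=np.int64)))


def census_frame(c: Census, decimals: int = 1) -> pd.DataFrame:
    pct = c.percents(decimals)
    return pd.DataFrame(
        {
            "rank": list(c.counts),
            "count": list(c.counts.values()),
            "percent": [pct[r] for r in c.counts],
        }
    )


def chambers_to_jsonl(G: GroupSpec, chambers: list[Chamber]) -> str:
    lines = []
    for c in chambers:
        lines.append(
            json.dumps(
                {
                    "sign": list(c.sign),
                    "witness": weight_to_dict(G, c.witness),
                    "rank": c.rank,
                }
            )
        )
    return "\n".join(lines) + "\n"


def exponent_matrices_to_json(G: GroupSpec) -> str:
    """JSON dump of the two exponent matrices: rows labelled by
    (edge, element index), columns by the leaf-labelling triples."""
    from .sunlet import consistent_labellings, exponent_matrices, parameter_indices

    M1, M2 = exponent_matrices(G)
    return json.dumps(
        {
            "rows": [[pi.edge, G.index(pi.elem)] for pi in parameter_indices(G)],
            "columns": [
                [G.index(lab.g1), G.index(lab.g2), G.index(lab.g3)]
                for lab in consistent_labellings(G)
            ],
            "m1": M1.tolist(),
            "m2": M2.tolist(),
        }
    )


def adjacency_edges_frame(graph) -> pd.DataFrame:
    """Chamber adjacency as an edge list: chamber indices plus the index
    of the crossed hyperplane (0 is the mu0 hyperplane)."""
    rows = [
        {"chamber_a": i, "chamber_b": j, "hyperplane": data["hyperplane"]}
        for i, j, data in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["chamber_a", "chamber_b", "hyperplane"])


def certificate_to_dict(cert: DimensionCertificate) -> dict[str, Any]:
    return {
        "group": {"factors": list(cert.group.factors)},
        "dimension": cert.dimension,
        "rank": cert.rank,
        "upper_bound": cert.upper_bound,
        "ambient": cert.ambient,
        "method": cert.method,
        "weights": weight_to_dict(cert.group, cert.rw),
    }
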