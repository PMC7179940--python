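"""Shared fixtures: tiny in-memory genotype matrices and VCF writers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omixalign import GenotypeMatrix
from omixalign.pair_graph import DataNode, Group, PairEdge

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##contig=<ID=X>
##contig=<ID=Y>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, records):
    """Write a minimal VCF; records are (chrom, pos, ref, alt, [gt, ...])."""
    lines = [VCF_HEADER.format(samples="\t".join(samples))]
    for chrom, pos, ref, alt, gts in records:
        fields = [str(chrom), str(pos), ".", ref, alt, ".", "PASS", ".", "GT"]
        fields.extend(gts)
        lines.append("\t".join(fields) + "\n")
    path.write_text("".join(lines))
    return path


def make_matrix(calls, omics_type="omicsA", data_ids=None, chrom="1", start_pos=100):
    """GenotypeMatrix from a (n_loci, n_data) array of {0,1,2,-1} calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_data = calls.shape
    if data_ids is None:
        data_ids = [f"{omics_type}_d{j}" for j in range(n_data)]
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * n_loci,
            "pos": [start_pos + 10 * i for i in range(n_loci)],
            "ref": ["A"] * n_loci,
            "alt": ["G"] * n_loci,
        }
    )
    return GenotypeMatrix(omics_type, list(data_ids), loci, calls)


def make_group(ids, omics=None, sexes=None, priorities=None, complete=True,
               group_id=1):
    """Build a fully connected group of nodes with the given observed IDs.

    ``omics`` defaults to one distinct omics type per node (one data per
    platform, the common case).  ``sexes`` gives (reported, genetic) pairs.
    """
    n = len(ids)
    omics = omics or [f"omics{i + 1}" for i in range(n)]
    sexes = sexes or [("male", "male")] * n
    priorities = priorities or [0.5] * n
    nodes = [
        DataNode(ids[i], omics[i], reported_sex=sexes[i][0],
                 snp_sex=sexes[i][1], omics_priority=priorities[i])
        for i in range(n)
    ]
    edges = []
    if complete:
        for i in range(n):
            for j in range(i + 1, n):
                edges.append(PairEdge(nodes[i], nodes[j], score=1.0))
    return Group(group_id, nodes, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
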