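"""Species-level (vOTU) and genus-level clustering.

vOTUs follow the consensus species definition for uncultivated viruses:
greedy clustering at >=95% average nucleotide identity over >=85% of the
shorter contig, longest contig first. ANI is measured fragment-wise
(fastANI-style): the shorter sequence is cut into fixed-size fragments and
each fragment is placed at its best window in the longer sequence by banded
edit-distance alignment (edlib).

Genus-level clusters use a gene-sharing network: genomes are nodes, and a
pair is connected when the number of protein clusters (PCs) they share is
unexpectedly large under a hypergeometric null, as in gene-sharing network
taxonomies of the vConTACT family. Clusters are connected components of the
thresholded graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .io import ContigRecord

log = logging.getLogger("hadalvir")


@dataclass
class VOtu:
    votu_id: str
    representative: str
    members: list          # contig ids, representative first
    member_metrics: dict   # contig_id -> (ani %, af)


@dataclass
class GenusCluster:
    cluster_id: str
    members: list


def _mask_ns(query: str, target: str) -> tuple[str, str]:
    # N must count as a mismatch even against another N.
    return query.replace("N", "N"), target.replace("N", "M")


def pairwise_ani(
    a: str,
    b: str,
    fragment: int = 500,
    fragment_identity_min: float = 80.0,
) -> tuple[float, float]:
    """Fragment-based (ANI %, aligned fraction of the shorter sequence).

    The shorter sequence is tiled into non-overlapping ``fragment``-nt
    pieces (the final window is right-anchored so the whole sequence is
    covered); each piece is aligned to its best window in the longer
    sequence by infix edit-distance alignment with the band set so that any
    fragment at or above ``fragment_identity_min`` identity is measured
    exactly. Fragments reaching that identity count as aligned; ANI is the
    mean identity over aligned fragments and AF the covered fraction of the
    shorter sequence. Symmetric by construction (the shorter always
    fragments). Sequences shorter than one fragment fall back to a single
    full-length alignment.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    short, long_ = _mask_ns(short, long_)
    n = len(short)

    if n < fragment:
        windows = [(0, n)]
    else:
        windows = [(s, s + fragment) for s in range(0, n - fragment + 1, fragment)]
        tail = n - windows[-1][1]
        if tail > 0:
            windows.append((n - fragment, n))  # right-anchored, credits the tail

    identities: list[float] = []
    covered = 0
    prev_end = 0
    for start, end in windows:
        piece = short[start:end]
        k = math.ceil(len(piece) * (1 - fragment_identity_min / 100))
        res = edlib.align(piece, long_, mode="HW", task="distance", k=k)
        dist = res["editDistance"]
        if dist < 0:
            prev_end = max(prev_end, end)
            continue
        identity = 100.0 * (1 - dist / len(piece))
        if identity >= fragment_identity_min:
            identities.append(identity)
            covered += end - max(start, prev_end)
        prev_end = max(prev_end, end)

    if not identities:
        return 0.0, 0.0
    ani = sum(identities) / len(identities)
    af = covered / n
    return ani, af


def greedy_species_cluster(
    contigs: Sequence[ContigRecord],
    ani_min: float = 95.0,
    af_min: float = 0.85,
    fragment: int = 500,
    fragment_identity_min: float = 80.0,
) -> list[VOtu]:
    """Greedy longest-first clustering into vOTUs.

    Contigs are sorted by length descending (ties by id ascending); each
    joins the first existing cluster whose representative satisfies
    ani >= ani_min and af >= af_min, else founds a new cluster. The
    representative is therefore always the longest member. Membership
    thresholds are re-asserted on every assignment.
    """
    if not contigs:
        raise ValueError("no contigs to cluster")
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    reps: list[ContigRecord] = []
    votus: list[VOtu] = []
    for contig in ordered:
        placed = False
        for rep, votu in zip(reps, votus):
            ani, af = pairwise_ani(contig.sequence, rep.sequence,
                                   fragment=fragment,
                                   fragment_identity_min=fragment_identity_min)
            if ani >= ani_min and af >= af_min:
                votu.members.append(contig.contig_id)
                votu.member_metrics[contig.contig_id] = (ani, af)
                placed = True
                break
        if not placed:
            votu = VOtu(f"vOTU_{len(votus) + 1:05d}", contig.contig_id,
                        [contig.contig_id],
                        {contig.contig_id: (100.0, 1.0)})
            reps.append(contig)
            votus.append(votu)
    for votu in votus:  # invariant check: thresholds hold for every member
        for member, (ani, af) in votu.member_metrics.items():
            assert ani >= ani_min and af >= af_min, (votu.votu_id, member)
    return votus


def votus_to_frame(votus: Sequence[VOtu]) -> pd.DataFrame:
    rows = []
    for v in votus:
        for member in v.members:
            ani, af = v.member_metrics[member]
            rows.append({
                "votu_id": v.votu_id, "member": member,
                "is_representative": int(member == v.representative),
                "ani": round(ani, 3), "af": round(af, 4),
            })
    return pd.DataFrame(rows, columns=["votu_id", "member",
                                       "is_representative", "ani", "af"])


# ---------------------------------------------------------------------------
# Gene-sharing genus network

def shared_pc_pvalue(m_universe: int, a: int, b: int, c: int) -> float:
    """Hypergeometric tail P(shared PCs >= c) for genomes with a and b PCs.

    P = sum_{i=c..min(a,b)} C(b,i) C(M-b, a-i) / C(M, a).
    """
    if c > min(a, b):
        raise ValueError(f"shared PCs {c} exceeds min({a}, {b}): inconsistent input")
    if c < 0 or a > m_universe or b > m_universe:
        raise ValueError("inconsistent PC counts")
    return float(hypergeom.sf(c - 1, m_universe, b, a))


def gene_sharing_edges(
    pc_membership: Mapping[str, str],
    genome_of: Mapping[str, str],
    score_min: float = 1.0,
) -> pd.DataFrame:
    """Significance-weighted edges between genomes sharing protein clusters.

    Edge score = -log10(P * n_pairs), a Bonferroni-style correction over the
    N(N-1)/2 genome pairs; edges with score >= score_min are kept.
    """
    missing = set(pc_membership) - set(genome_of)
    if missing:
        raise ValueError(f"proteins without a genome: {sorted(missing)[:5]}")
    pcs_by_genome: dict[str, set] = {}
    for protein, pc in pc_membership.items():
        pcs_by_genome.setdefault(genome_of[protein], set()).add(pc)
    genomes = sorted(pcs_by_genome)
    m_universe = len({pc for pcs in pcs_by_genome.values() for pc in pcs})
    n_pairs = len(genomes) * (len(genomes) - 1) // 2
    rows = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            sa, sb = pcs_by_genome[ga], pcs_by_genome[gb]
            c = len(sa & sb)
            if c == 0:
                continue
            p = shared_pc_pvalue(m_universe, len(sa), len(sb), c)
            corrected = p * n_pairs
            score = -math.log10(corrected) if corrected > 0 else math.inf
            if score >= score_min:
                rows.append({"genome_a": ga, "genome_b": gb, "shared_pcs": c,
                             "p_value": p, "score": score})
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "shared_pcs",
                                       "p_value", "score"])


def genus_clusters(
    edges: pd.DataFrame,
    genomes: Sequence[str],
    count_singletons: bool = True,
) -> tuple[list[GenusCluster], list[str]]:
    """Connected components of the thresholded gene-sharing graph.

    Returns (clusters, singletons). Singleton genomes found no significant
    edge; whether they count as genera is the caller's reporting choice
    (``count_singletons`` merely controls whether they are also emitted as
    one-member clusters).
    """
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    for _, row in edges.iterrows():
        graph.add_edge(row["genome_a"], row["genome_b"])
    clusters: list[GenusCluster] = []
    singletons: list[str] = []
    components = sorted((sorted(comp) for comp in nx.connected_components(graph)),
                        key=lambda comp: (-len(comp), comp[0]))
    idx = 1
    for comp in components:
        if len(comp) == 1:
            singletons.append(comp[0])
            if not count_singletons:
                continue
        clusters.append(GenusCluster(f"genus_{idx:05d}", comp))
        idx += 1
    return clusters, singletons
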