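"""Two-stage nonredundancy workflow for antibody-antigen complexes.

Stage 1 clusters heavy, light, and antigen chain sequences individually by
greedy incremental clustering at 0.95 identity (CD-HIT convention: sequences
sorted by length descending, identity measured over the shorter sequence,
each sequence joining the first cluster whose representative is close
enough). Each complex is labelled by its chain cluster ids
(``heavy_light_antigen1:antigen2``; a missing light chain is ``-``), and the
first complex per label is kept.

Stage 2 rescues complexes that share a label but bind a *different site*:
each provisionally redundant complex is compared to the retained members of
its label group by interface similarity — the fraction of shared
paratope+epitope residue keys, computed from each side and averaged. A
complex whose similarity to every retained member stays below the 0.90
threshold is reinstated as nonredundant (antibodies binding the same antigen
on different epitopes are genuinely distinct complexes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .sasa import InterfaceSet

__all__ = [
    "ClusterAssignment",
    "SimilarityResult",
    "DedupResult",
    "sequence_identity",
    "greedy_cluster",
    "label_complex",
    "interface_similarity",
    "deduplicate",
]

IDENTITY_THRESHOLD = 0.95
SIMILARITY_THRESHOLD = 0.90


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(a: str, b: str) -> float:
    """Identical aligned positions divided by the shorter sequence length."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if a == b:
        return 1.0
    alignment = _aligner().align(a, b)[0]
    identical = sum(
        1
        for (sa, ea), (sb, eb) in zip(*alignment.aligned)
        for i in range(ea - sa)
        if a[sa + i] == b[sb + i]
    )
    return identical / min(len(a), len(b))


@dataclass
class ClusterAssignment:
    role: str
    cluster_of: dict[str, int]            # sequence id -> cluster id
    representative: dict[int, str]        # cluster id -> representative sequence id
    sequences: dict[str, str] = field(default_factory=dict)


def greedy_cluster(
    sequences: dict[str, str],
    threshold: float = IDENTITY_THRESHOLD,
    role: str = "",
) -> ClusterAssignment:
    """Greedy incremental clustering of sequences at an identity threshold.

    Sequences are processed longest-first (ties broken by id) so the
    representative of each cluster is its longest member; a sequence joins
    the first existing cluster whose representative reaches the threshold,
    else founds a new cluster. Deterministic regardless of input order.
    """
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for id {sid!r}")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    cluster_of: dict[str, int] = {}
    representative: dict[int, str] = {}
    for sid in order:
        seq = sequences[sid]
        for cid in sorted(representative):
            if sequence_identity(sequences[representative[cid]], seq) >= threshold:
                cluster_of[sid] = cid
                break
        else:
            cid = len(representative)
            representative[cid] = sid
            cluster_of[sid] = cid
    return ClusterAssignment(
        role=role, cluster_of=cluster_of, representative=representative,
        sequences=dict(sequences),
    )


def label_complex(
    heavy_cluster: int | None,
    light_cluster: int | None,
    antigen_clusters: list[int],
) -> str:
    """Cluster-id label ``heavy_light_ag1:ag2`` (missing light chain -> '-')."""
    if heavy_cluster is None:
        raise ValueError("complex has no clustered heavy chain")
    if not antigen_clusters:
        raise ValueError("complex has no clustered antigen chain")
    light = "-" if light_cluster is None else str(light_cluster)
    antigens = ":".join(str(c) for c in sorted(antigen_clusters))
    return f"{heavy_cluster}_{light}_{antigens}"


@dataclass
class SimilarityResult:
    id_a: str
    id_b: str
    fraction_a: float   # shared / A's interface residues
    fraction_b: float   # shared / B's interface residues
    overall: float      # mean of the two directional fractions
    is_redundant: bool
    flagged_empty: bool = False


def _key_set(interface) -> frozenset:
    if isinstance(interface, InterfaceSet):
        return interface.similarity_keys
    return frozenset(interface)


def interface_similarity(
    a, b, id_a: str = "A", id_b: str = "B",
    threshold: float = SIMILARITY_THRESHOLD,
    per_side: bool = False,
) -> SimilarityResult:
    """Directional interface similarity between two complexes.

    Interfaces are compared as sets of residue keys (side, IMGT position,
    insertion, amino acid): the shared fraction is computed from each
    complex's perspective and averaged. With ``per_side=True`` paratope and
    epitope fractions are computed separately and the overall score is the
    mean of all four directional fractions.
    """
    if per_side and isinstance(a, InterfaceSet) and isinstance(b, InterfaceSet):
        fracs_a, fracs_b = [], []
        for selector in ("paratope", "epitope"):
            ka = frozenset(k for k in _key_set(a) if k[0] == selector)
            kb = frozenset(k for k in _key_set(b) if k[0] == selector)
            shared = ka & kb
            fracs_a.append(len(shared) / len(ka) if ka else 0.0)
            fracs_b.append(len(shared) / len(kb) if kb else 0.0)
        fraction_a = sum(fracs_a) / len(fracs_a)
        fraction_b = sum(fracs_b) / len(fracs_b)
        empty = not (_key_set(a) and _key_set(b))
    else:
        ka, kb = _key_set(a), _key_set(b)
        empty = not (ka and kb)
        shared = ka & kb
        fraction_a = len(shared) / len(ka) if ka else 0.0
        fraction_b = len(shared) / len(kb) if kb else 0.0
    overall = 0.0 if empty else (fraction_a + fraction_b) / 2.0
    return SimilarityResult(
        id_a=id_a, id_b=id_b,
        fraction_a=fraction_a, fraction_b=fraction_b,
        overall=overall,
        is_redundant=overall >= threshold,
        flagged_empty=empty,
    )


@dataclass
class DedupResult:
    nonredundant: list[str]
    redundant: list[str]
    stage1_representatives: int
    reinstated: int

    @property
    def final_total(self) -> int:
        return len(self.nonredundant)


def deduplicate(
    entries: list[tuple[str, str]],
    interfaces: dict,
    threshold: float = SIMILARITY_THRESHOLD,
    per_side: bool = False,
) -> DedupResult:
    """Two-stage redundancy removal with accounting.

    ``entries`` is an ordered list of (complex_id, label); ``interfaces``
    maps complex ids to InterfaceSets (or plain key sets). Stage 1 keeps the
    first complex of each label (stable input order). Stage 2 walks the
    remaining complexes in input order and reinstates any whose interface
    similarity to *every* already-retained member of its label group is
    below the threshold; reinstated complexes immediately join the
    comparison pool for later members.
    """
    retained_by_label: dict[str, list[str]] = {}
    nonredundant: list[str] = []
    redundant: list[str] = []
    reinstated = 0
    stage1 = 0
    for cid, label in entries:
        pool = retained_by_label.setdefault(label, [])
        if not pool:
            pool.append(cid)
            nonredundant.append(cid)
            stage1 += 1
            continue
        similar = any(
            interface_similarity(
                interfaces[cid], interfaces[other], cid, other,
                threshold=threshold, per_side=per_side,
            ).is_redundant
            for other in pool
        )
        if similar:
            redundant.append(cid)
        else:
            pool.append(cid)
            nonredundant.append(cid)
            reinstated += 1
    return DedupResult(
        nonredundant=nonredundant,
        redundant=redundant,
        stage1_representatives=stage1,
        reinstated=reinstated,
    )
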