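"""Synthetic planted-partition E-value data.

Real all-against-all BLAST output over a set of protein families has a
characteristic two-population structure: pairs within a family report
small E-values (strong similarity), pairs across families report large
ones near the reporting ceiling, and many pairs are not reported at
all.  The generator emulates exactly this at the E-value level — it
does not simulate sequences — by planting clusters and drawing
log10 E-values from two Gaussians, one intra- and one inter-cluster,
with independent report probabilities.  Gold labels come along for
free, so recovery experiments need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from specfam.graph import Partition
from specfam.similarity import EValueRecord

__all__ = [
    "PlantedSpec",
    "generate_planted",
    "generate_training_pairs",
    "toy_worked_example",
]

#: E-values are clipped to this range: 1e-180 matches the similarity
#: model's log-transform floor, 10 is the default BLAST report ceiling.
EVALUE_CLIP = (1e-180, 10.0)


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted-partition E-value generator.

    ``intra_mean_log10 = -50`` with sd 10 puts within-family hits at
    E ~ 1e-50, far below any clustering threshold, while
    ``inter_mean_log10 = 0`` (sd 1) keeps cross-family hits near E = 1,
    mimicking the clearly separated intra/inter E-value populations of
    curated superfamily data.  Densities 0.9 / 0.05 reflect that BLAST
    reports most within-family pairs but few spurious cross-family ones.
    """

    cluster_sizes: tuple[int, ...] = (20, 20, 20)
    intra_mean_log10: float = -50.0
    intra_sd_log10: float = 10.0
    inter_mean_log10: float = 0.0
    inter_sd_log10: float = 1.0
    edge_density_intra: float = 0.9
    edge_density_inter: float = 0.05
    asymmetric: bool = False
    asymmetry_sd_log10: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        for d in (self.edge_density_intra, self.edge_density_inter):
            if not (0 <= d <= 1):
                raise ValueError("edge densities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return sum(self.cluster_sizes)


def _clip_evalue(log10_e: np.ndarray) -> np.ndarray:
    lo, hi = EVALUE_CLIP
    return np.clip(10.0 ** np.clip(log10_e, -np.inf, np.log10(hi)), lo, hi)


def generate_planted(spec: PlantedSpec) -> tuple[list[EValueRecord], Partition]:
    """Draw a planted-partition E-value list and its gold partition.

    Every intra-cluster pair is reported with probability
    ``edge_density_intra`` at E = 10**N(intra mean, sd); inter-cluster
    pairs analogously.  With ``asymmetric=True`` both query directions
    are emitted with independently jittered E-values, exercising the
    min-E-value symmetrization rule downstream.  Deterministic under
    the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    gold_labels: list[int] = []
    for c, size in enumerate(spec.cluster_sizes):
        for k in range(size):
            ids.append(f"c{c}_{k:03d}")
            gold_labels.append(c)
    labels = np.array(gold_labels)
    n = len(ids)

    records: list[EValueRecord] = []
    for i in range(n):
        for j in range(i + 1, n):
            intra = labels[i] == labels[j]
            density = spec.edge_density_intra if intra else spec.edge_density_inter
            if rng.random() >= density:
                continue
            mean = spec.intra_mean_log10 if intra else spec.inter_mean_log10
            sd = spec.intra_sd_log10 if intra else spec.inter_sd_log10
            base = rng.normal(mean, sd)
            if spec.asymmetric:
                jitter = rng.normal(0.0, spec.asymmetry_sd_log10, size=2)
                e_fwd, e_rev = _clip_evalue(np.array([base, base]) + jitter)
                records.append(EValueRecord(ids[i], ids[j], float(e_fwd)))
                records.append(EValueRecord(ids[j], ids[i], float(e_rev)))
            else:
                e = float(_clip_evalue(np.array([base]))[0])
                records.append(EValueRecord(ids[i], ids[j], e))

    gold = Partition.from_labels(ids, gold_labels)
    return records, gold


def generate_training_pairs(
    spec: PlantedSpec, n_per_class: int = 10_000
) -> list[tuple[float, str]]:
    """Labelled (evalue, intra/inter) samples for fitting the logistic model.

    Draws ``n_per_class`` E-values from each of the spec's two log10
    distributions — the same 10,000 + 10,000 design used to train the
    similarity model on curated superfamily data.
    """
    rng = np.random.default_rng(spec.seed)
    intra = _clip_evalue(
        rng.normal(spec.intra_mean_log10, spec.intra_sd_log10, n_per_class)
    )
    inter = _clip_evalue(
        rng.normal(spec.inter_mean_log10, spec.inter_sd_log10, n_per_class)
    )
    pairs = [(float(e), "intra") for e in intra]
    pairs += [(float(e), "inter") for e in inter]
    return pairs


# Fixed 12-sequence, 3-family instance used in examples and docs.  All
# intra-family pairs are reported well below 1e-6; the three cross-family
# links sit near E = 1 so they survive into the affinity matrix as weak
# edges but never into a thresholded graph.
_TOY_EVALUES: tuple[tuple[str, str, float], ...] = (
    # family gl (globin-like stand-in)
    ("gl1", "gl2", 1e-42), ("gl1", "gl3", 3e-38), ("gl1", "gl4", 2e-35),
    ("gl2", "gl3", 5e-40), ("gl2", "gl4", 1e-33), ("gl3", "gl4", 4e-37),
    # family ef (EF-hand stand-in)
    ("ef1", "ef2", 2e-28), ("ef1", "ef3", 8e-25), ("ef1", "ef4", 1e-22),
    ("ef2", "ef3", 6e-27), ("ef2", "ef4", 3e-24), ("ef3", "ef4", 9e-26),
    # family tx (toxin-like stand-in)
    ("tx1", "tx2", 1e-30), ("tx1", "tx3", 2e-29), ("tx1", "tx4", 7e-28),
    ("tx2", "tx3", 4e-31), ("tx2", "tx4", 5e-29), ("tx3", "tx4", 1e-27),
    # weak cross-family hits, all far above the 1e-6 threshold
    ("gl1", "ef1", 0.7), ("ef2", "tx1", 1.5), ("gl3", "tx2", 2.0),
)


def toy_worked_example() -> tuple[list[EValueRecord], Partition]:
    """A fixed hand-written 12-sequence, 3-family instance.

    Three families of four sequences each with strong intra-family hits
    (E <= 1e-22) and three weak cross-family hits (E >= 0.7).  Used in
    the documentation's worked example; thresholded clustering at 1e-6
    and spectral clustering with K = 3 both recover the three families.
    """
    records = [EValueRecord(q, s, e) for q, s, e in _TOY_EVALUES]
    gold = Partition.from_clusters(
        [["gl1", "gl2", "gl3", "gl4"],
         ["ef1", "ef2", "ef3", "ef4"],
         ["tx1", "tx2", "tx3", "tx4"]]
    )
    return records, gold
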