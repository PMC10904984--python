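"""QC-filter a small batch of MAGs and dereplicate them into SGBs.

Three MAGs fail quality control (completeness must exceed 50%, contamination
must stay below 5%); the survivors are clustered at 5% genome distance from
k-mer sketch distances, and each cluster's representative is the MAG with
the best quality score Q = completeness - 5 x contamination.
"""

import itertools

import numpy as np

from wildgut import DistanceMatrix, MagRecord, dereplicate, qc_filter, sketch_distance

rng = np.random.default_rng(0)

mags = [
    MagRecord("magA1", 96.0, 0.8, genome_size=2_400_000),
    MagRecord("magA2", 88.0, 1.5, genome_size=2_300_000),   # same species as magA1
    MagRecord("magB1", 72.0, 3.2, genome_size=3_100_000),
    MagRecord("magC1", 49.0, 0.5, genome_size=1_900_000),   # too incomplete
    MagRecord("magC2", 80.0, 6.5, genome_size=2_000_000),   # too contaminated
]

kept = qc_filter(mags)
print(f"{len(kept)} of {len(mags)} MAGs pass QC:", [m.mag_id for m in kept])

# k-mer sketches: magA1 and magA2 share most k-mers, magB1 shares none
kmers = {
    "magA1": set(range(0, 1000)),
    "magA2": set(range(20, 1020)),
    "magB1": set(range(5000, 6000)),
}
ids = [m.mag_id for m in kept]
d = np.zeros((len(ids), len(ids)))
for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
    d[i, j] = d[j, i] = sketch_distance(kmers[a], kmers[b], k=21)
    print(f"sketch distance {a}-{b}: {d[i, j]:.4f}")

clusters = dereplicate(kept, DistanceMatrix(ids, d), threshold=0.05)
print(f"{len(clusters)} species-level genome bins:")
for c in clusters:
    print(f"  {c.sgb_id}: members={sorted(c.member_mag_ids)} "
          f"representative={c.representative_mag_id}")
# magA1/magA2 merge (distance under 5%) with magA1 chosen as representative
# (higher quality score); magB1 stays its own species.
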