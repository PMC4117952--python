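"""Simulate a genome with planted poly(A) sites, curate tags, call PACs.

Prints the curation cascade (how many reads survive mate-pairing and the
internal-priming filter) and how exactly the PAC summits recover the
planted cleavage sites.
"""

import polyaflow as pf
from polyaflow import simulate as sim
from polyaflow.params import MTR_LIKE

cfg = pf.SimConfig(seed=42, microheterogeneity_sd=3.0)
genome, transcripts, models, truth = sim.simulate_genome(cfg)
tags = sim.simulate_tags(genome, models, truth, cfg, unpaired_rate=0.05)

kept, discarded, report = pf.curate_tags([t.as_mapped_tag() for t in tags],
                                         genome, MTR_LIKE)
print("curation cascade (read counts):")
for stage, n in report.rows():
    print(f"  {stage:45s} {n}")

pacs = pf.cluster_tags(kept, MTR_LIKE)
print(f"\n{len(pacs)} PACs called from {len(truth.planted_sites)} planted sites")

summits = {}
for p in pacs:
    summits.setdefault((p.chrom, p.strand), []).append(p.summit)
hits = sum(1 for s in truth.planted_sites
           if min((abs(x - s.coord) for x in summits.get((s.chrom, s.strand), [])),
                  default=999) <= 5)
print(f"summits within 5 nt of a planted site: {hits}/{len(truth.planted_sites)}")
print("\nEach PAC groups cleavage positions chained at <24 nt; the summit is")
print("the best-supported position, so it should sit on the planted site up")
print("to the simulated microheterogeneity (sd = 3 nt).")
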