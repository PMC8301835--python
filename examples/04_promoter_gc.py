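"""TSS-anchored GC-content profiles.

The synthetic genome carries a linear GC gradient from the replication
origin (GC-rich, 0.56) to the terminus (GC-poor, 0.48).  Extracting the
promoter context (−300..+200 bp around each TSS, coding strand) and
averaging per-position GC across origin-proximal vs terminus-proximal
gene sets recovers that planted difference.
"""
import numpy as np

import couplonscan as cs
from couplonscan.annotation import circular_distance

spec = cs.SimulationSpec(seed=4, regulators=())
ann, seq = cs.generate_genome(spec)

d = circular_distance(ann.positions(), 0, spec.chromosome_length)
ids = np.array(ann.gene_ids)
order = np.argsort(d)
ori_set, ter_set = set(ids[order[:200]]), set(ids[order[-200:]])

contexts = cs.extract_contexts(seq, ann, upstream=300, downstream=200)
by_id = {c.gene_id: c for c in contexts}
prof_all = cs.gc_profile(contexts, smoothing=21, set_name="all")
prof_ori = cs.gc_profile([by_id[g] for g in sorted(ori_set)], smoothing=21, set_name="ori")
prof_ter = cs.gc_profile([by_id[g] for g in sorted(ter_set)], smoothing=21, set_name="ter")

table, mean_diff = cs.compare_gc_profiles(prof_ori, prof_ter, prof_all)
print(f"Mean GC over the [-300, +200) span, all {prof_all.n_sequences} genes: "
      f"{np.nanmean(prof_all.values):.3f}")
print(f"Origin-proximal genes:   {np.nanmean(prof_ori.values):.3f}")
print(f"Terminus-proximal genes: {np.nanmean(prof_ter.values):.3f}")
print(f"Mean Ori - Ter difference: {mean_diff:+.3f} "
      f"(planted gradient spans {spec.gc_ori - spec.gc_ter:.2f})")
print("Positive difference = promoters near the origin are GC-richer, i.e.")
print("thermodynamically more stable duplexes, exactly as constructed.")
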