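"""Classify the structural motif at pivot sites.

Generates the four motif fixtures — a pure Watson-Crick duplex, a G-U
wobble, a 2-nt bulge and a three-way junction — and classifies each pivot
site from geometric base-pair annotation alone.
"""

from rnapivot import annotate_pairs, classify_site
from rnapivot.synthetic import HingeSpec, make_hinge_pair, make_junction

for motif in ("GU_wobble", "bulge:2", "three_way_junction"):
    model, _, truth = make_hinge_pair(HingeSpec(motif_at_pivot=motif))
    records = annotate_pairs(model)
    order = [r.author_number for r in model.chains["A"]]
    call = classify_site(records, truth.pivot_residue, order)
    print(f"{motif:20s} -> site {truth.pivot_residue:3d} classified as "
          f"{call.motif_class}")

junction = make_junction(n_arms=3, arm_len=4)
records = annotate_pairs(junction)
order = [r.author_number for r in junction.chains["A"]]
site = int(junction.metadata["junction_residues"].split(",")[0])
call = classify_site(records, site, order)
print(f"{'standalone junction':20s} -> site {site:3d} classified as "
      f"{call.motif_class}")
# Each fixture classifies to its true class; precedence is
# wobble > non-canonical pair > bulge > junction.
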