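"""Signature strata assignment and high-confidence variant filtering.

Classifies synthetic signature-probability profiles into mutational strata
with the k-nearest-neighbour majority vote (k=30, m=25), then applies the
focal-CNA callers and the SNV/breakpoint filters to boundary fixtures.
"""

from tmeco.genomic import (
    call_homozygous_deletions_wgs,
    call_panel_focal_events,
    filter_breakpoints,
    filter_snvs,
    knn_signature_assign,
)
from tmeco.synthetic import (
    simulate_breakpoints,
    simulate_segments,
    simulate_signature_profiles,
    simulate_variants,
)

centroids = {
    "HRD-Dup": [0.8, 0.1, 0.05, 0.05],
    "HRD-Del": [0.1, 0.8, 0.05, 0.05],
    "FBI": [0.05, 0.05, 0.8, 0.1],
}
reference, ref_labels = simulate_signature_profiles(40, centroids, spread=0.03, seed=0)
test, truth = simulate_signature_profiles(10, centroids, spread=0.03, seed=1)
assigned = knn_signature_assign(test, reference, ref_labels, k=30, m=25)
print("strata recovery:", (assigned == truth).mean())
# well-separated clouds are recovered perfectly; ambiguous profiles near a
# decision boundary would fall below the 25-vote bar and become Undetermined

wgs = simulate_segments("wgs")
wgs["homdel"] = call_homozygous_deletions_wgs(wgs)
print(wgs.to_string(index=False))
# only segments >= 10 kb with mean copy number < 0.5 are called

panel = simulate_segments("panel")
panel["event"] = call_panel_focal_events(panel)
print(panel.to_string(index=False))

variants, blacklist, known = simulate_variants()
kept = filter_snvs(variants, blacklist, known)
print(f"SNVs kept: {len(kept)}/{len(variants)} ->", list(zip(kept['chrom'], kept['pos'])))
# survivors were called by both callers at probability >= 0.9 outside
# blacklisted regions and are not known germline variants

bps, bp_blacklist = simulate_breakpoints()
kept_bp = filter_breakpoints(bps, bp_blacklist)
print(f"breakpoints kept: {len(kept_bp)}/{len(bps)} ->", kept_bp["breakpoint_id"].tolist())
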