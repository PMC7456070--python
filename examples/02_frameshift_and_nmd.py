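"""Simulate the -1 slip and apply the 50-nt exon-junction NMD rule.

After a -1 slip at a slippery site the ribosome resumes translation one
nucleotide upstream, in the -1 frame, and usually soon encounters a
premature termination codon (PTC). If that PTC lies at least 50 nt
upstream of the next exon-exon junction, the transcript is predicted to
be degraded by nonsense-mediated decay (NMD).

The transcript below is constructed so the -1-frame PTC ends exactly
52 nt upstream of the next junction: above the 50-nt threshold, so NMD
is predicted.
"""
from prfscan import TranscriptModel, find_slippery_sites, frameshift_outcome, predict_nmd

model = TranscriptModel(
    transcript_id="ptc_junction_demo",
    cds="AUGCAAAAUUUUAAGUAA",
    cds_offset=0,
    junctions=(66,),  # transcript coordinate of the first base after the junction
)

site = next(s for s in find_slippery_sites(model) if s.trna_class == "phe")
print(f"Slippery site: start={site.start}, heptamer={site.heptamer}, class={site.trna_class}")

out = frameshift_outcome(model, site)
print(f"-1 frame PTC found: {out.ptc_found} at CDS position {out.ptc_start}")
print(f"Distance from PTC to next exon-exon junction: {out.dist_to_next_junction} nt")
print(f"NMD predicted (>= 50 nt rule): {predict_nmd(out)}")
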