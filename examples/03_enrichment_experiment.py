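"""Full synthetic enrichment experiment with negative controls.

Generates a synthetic transcriptome in which transcripts carrying a
planted Phe-type (UUUU/C) -1 PRF signal are down-regulated with a true
odds ratio of 3, scans it, and runs the Fisher enrichment panel:

  - phe_uuuu_c    : transcripts with a passing Phe-type signal (the
                    hypothesis class - should be enriched among
                    down-regulated transcripts)
  - lys_aaaa_g    : passing Lys-type signals (negative control - planted
                    signals exist but are not linked to down-regulation)
  - no_phe_codon  : transcripts with no in-frame UUU/UUC codon at all
                    (negative control that cannot respond to a
                    Phe-tRNA-mediated mechanism)

Each class is tested against two comparators: up-regulated transcripts
and the full non-down background.
"""
import time

from prfscan import ScanConfig, control_panel, scan_transcriptome, summarize_de
from prfscan.simulate import SimulationConfig, generate_de_table, generate_transcriptome

cfg = SimulationConfig(n_transcripts=800, enrichment_odds_ratio=3.0, seed=123)
models, truth = generate_transcriptome(cfg)
de = generate_de_table(truth, cfg)

s = summarize_de(de)
print(
    f"Simulated {len(models)} transcripts: {s['down']} down, {s['up']} up, "
    f"{s['unchanged']} unchanged "
    f"({s['percent_down_of_changed']:.0f}% of changed are down)"
)

t0 = time.time()
scan_cfg = ScanConfig(seed=123, n_perm=50)
signals = scan_transcriptome(models, scan_cfg)
print(f"Scanned in {time.time() - t0:.1f} s; {sum(s.passes for s in signals)} passing signals")

print(f"\n{'class':14s} {'comparator':18s} {'odds_ratio':>10s} {'p':>10s}")
for r in control_panel(models, de, scan_cfg, signals=signals):
    print(
        f"{r.signal_class:14s} {r.comparator:18s} "
        f"{r.odds_ratio:10.2f} {r.p:10.2e}"
    )
print(
    "\nOnly the Phe class should reach significance; the Lys and"
    "\nno-Phe-codon controls stay near their null expectation."
)
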