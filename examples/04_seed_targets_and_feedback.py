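"""miR-1 seed matching on 3'UTRs and the YY1 <-> miR-1 feedback loop.

Uses the canonical muscle miRNA miR-1: its 7-nt seed (positions 2-8) is
GGAAUGU, whose reverse complement ACATTCC is the site searched on target
3'UTRs (Pax7, YY1). Mutating the site to GGGCCTT abolishes detection, and a
miRNA that targets its own transcriptional repressor closes a feedback loop.
"""

import mircircuit as mc

mir1 = mc.MatureMiRNA("miR-1", "UGGAAUGUAAAGAAGUAUGUAU")
print(f"miR-1 seed (2-8): {mc.seed_of(mir1)}  -> UTR site {mc.reverse_complement(mc.seed_of(mir1).replace('U', 'T'))}")

pax7_utr = ("G" * 1557) + "ACATTCC" + ("G" * 536) + "ACATTCC" + ("G" * 100)
sites = mc.find_seed_sites(mir1, pax7_utr, "Pax7")
print("Pax7 sites:", [(s.position, s.site_type) for s in sites])

yy1_utr = ("G" * 440) + "ACATTCC" + ("G" * 100)
print("YY1 site:", [(s.position, s.site_type) for s in mc.find_seed_sites(mir1, yy1_utr, "YY1")])
mutant = yy1_utr.replace("ACATTCC", "GGGCCTT")
print("YY1 mutant site:", mc.find_seed_sites(mir1, mutant, "YY1"))

net = mc.build_network("YY1", ["miR-1", "miR-133", "miR-206"],
                       {"miR-1": ["YY1", "Pax7", "HDAC4"]})
print("feedback loops through YY1:", mc.find_feedback_loops(net, "YY1"))
# Two sites on the Pax7 UTR, one on YY1's own UTR (none after mutation), and
# miR-1 is reported as the miRNA closing the TF <-> miRNA feedback loop.
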