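"""Filter amplicon base counts into candidate mutation calls.

Shows the three decision boundaries of the screen filter: the >= 10 read
coverage gate, the strictly-more-than-10% deviation trigger, and the
multi-allelic noise exclusion (a real mutation concentrates its
non-reference reads in one alternate base).
"""

from uorfscan import SiteBaseCount, call_site

examples = [
    ("clean 30% heterozygote", SiteBaseCount("S1", "c1", 100, "A",
                                             {"A": 28, "G": 12})),
    ("deviation exactly 10%", SiteBaseCount("S1", "c1", 101, "A",
                                            {"A": 90, "G": 10})),
    ("scattered noise 7/1/1/1", SiteBaseCount("S1", "c1", 102, "A",
                                              {"A": 7, "C": 1, "G": 1, "T": 1})),
    ("nine reads only", SiteBaseCount("S1", "c1", 103, "A",
                                      {"A": 5, "G": 4})),
    ("single-base deletion", SiteBaseCount("S1", "c1", 104, "A",
                                           {"A": 30, "DEL": 12})),
]

for label, site in examples:
    call = call_site(site)
    dev = "-" if call.deviation_fraction is None else f"{call.deviation_fraction:.0%}"
    print(f"{label:26s} -> {call.status:15s} deviation {dev:>4s} "
          f"top alt {call.top_alt_base or '-'}")

print()
print("A candidate needs >= 10 reads, deviation strictly above 10%, and a")
print("dominant alternate (>= 2/3 of non-reference reads). A heterozygous")
print("mutation in a 50%-pure tumor deviates in ~25% of reads, so it")
print("clears the 10% trigger comfortably.")
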