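"""From benefit episodes to a counting process and transition counts.

Gaps between registered episodes are employment; each person's at-risk
intervals tile their observation window exactly.  Transition types seen
fewer than 10 times are removed, with the interrupted spells treated as
unbroken.
"""

import worklife as wl

cohort = wl.generate_cohort(wl.default_config(scale=2000), seed=1)
events, intervals = wl.episodes_to_process(cohort.episodes, cohort.windows)
counts = wl.count_transitions(events, intervals)

print("transition counts (rows: from, columns: to, plus censored):")
print(counts.counts.to_string())
print(f"\ntotal transitions: {counts.total_transitions}")
print(f"censored spells (alive and at risk at window end): "
      f"{counts.total_censored}")

filt = wl.filter_rare_transitions(events, intervals, counts, min_count=10)
print(f"\nrare transition types removed (<10 events): {filt.removed}")
print(f"events retained: {len(filt.events)} of {len(events)}")
print("\nDiagonal cells are same-state re-episodes (a new spell of the")
print("same benefit); they are bookkeeping only and carry no intensity.")
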