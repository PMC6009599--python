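"""Classify genes by combining the TE and transcription calls.

A gene significantly induced at both levels is 'potentiated'; TE-up genes
with unchanged or reduced transcription form their own classes, as do
transcription-only changes.  The four-way Venn partition counts every
intersection region of the polysome-up / TE-up / T-up / T-down sets.
"""

from thx import (
    SimConfig,
    build_gem,
    call_significant,
    classify_genes,
    compute_te,
    differential_abundance,
    differential_te,
    simulate,
    venn_partition,
)

cfg = SimConfig(
    n_genes=400,
    n_replicates=4,
    group_sizes={
        "potentiated": 6,
        "te_up_t_unchanged": 10,
        "te_up_t_down": 5,
        "t_up_only": 8,
        "t_down_only": 15,
    },
    seed=3,
)
sim = simulate(cfg)
gem = build_gem(sim.experiment.tables)

te_rp = differential_te(compute_te(gem, "polysome", "total"), n_perm=1000, seed=1)
t_rp = differential_abundance(gem, "total", n_perm=1000, seed=2)
poly_rp = differential_abundance(gem, "polysome", n_perm=1000, seed=3)

te_up, te_down = call_significant(te_rp)
t_up, t_down = call_significant(t_rp)
poly_up, _ = call_significant(poly_rp)

classes = classify_genes(gem.row_ids, te_up, te_down, t_up, t_down)
print("response-class counts (truth in parentheses):")
truth_counts = sim.truth["class_label"].value_counts()
for cls, n in classes.value_counts().items():
    if cls != "none":
        print(f"  {cls:20s} {n:3d}  ({truth_counts.get(cls, 0)})")

regions = venn_partition({"polysome_up": poly_up, "te_up": te_up, "t_up": t_up, "t_down": t_down})
occupied = regions[regions["count"] > 0]
print(f"\nVenn: {len(occupied)} occupied regions, {regions['count'].sum()} genes in the union")
print(occupied.to_string(index=False))
# each row is one exclusive intersection region; counts sum to the union.
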