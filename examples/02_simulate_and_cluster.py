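"""Simulate a cohort with planted archetypes and recover them with Ward.

Generates a noise-free cohort of 347 patients carrying the four planted
response archetypes (58/87/138/64), classifies the realized visit
trajectories, clusters the 12 coded response features, and scores the
recovery against the hidden truth labels.  At noise 0 the adjusted Rand
index is 1.0 — the planted partition is recovered exactly.
"""

from phenoresp import (
    SimulationConfig,
    adjusted_rand_index,
    build_response_profile,
    cut_tree,
    distance_matrix,
    encode_matrix,
    select_k_by_gap,
    simulate_cohort,
    ward_linkage,
)
from phenoresp.response_rules import VisitRecord

config = SimulationConfig(n_enrolled=347, missing_rate=0.0, noise_rate=0.0,
                          seed=42)
result = simulate_cohort(config)

ages = result["baselines"].set_index("patient_id")["age_years"]
visits = {}
for r in result["visits"].itertuples(index=False):
    visits.setdefault(r.patient_id, []).append(VisitRecord(
        patient_id=r.patient_id, visit_index=int(r.visit_index),
        fev1_pp=r.fev1_pp, mef50_pp=r.mef50_pp, feno_ppb=r.feno_ppb,
        control_level=int(r.control_level)))
profiles = [build_response_profile(v, float(ages[pid]))
            for pid, v in visits.items()]
matrix, excluded = encode_matrix(profiles)

dendrogram = ward_linkage(distance_matrix(matrix),
                          leaf_names=matrix.patient_ids)
assignment = cut_tree(dendrogram, k=4)

truth = result["truth"].set_index("patient_id")["archetype"].to_dict()
ari = adjusted_rand_index(assignment.labels,
                          {p: truth[p] for p in assignment.labels})

print(f"coded matrix: {matrix.values.shape[0]} patients x "
      f"{matrix.values.shape[1]} response features")
print(f"cluster sizes at k=4: {sorted(assignment.sizes().values())}")
print(f"adjusted Rand index vs planted archetypes: {ari:.3f}")
print(f"advisory k from the merge-gap heuristic: "
      f"{select_k_by_gap(dendrogram, k_max=8)}")
print("\nARI 1.0 means every patient landed in its planted archetype; the "
      "sizes match the study's cluster sizes 58/87/138/64.")
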