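"""Link community structure to predictors: PERMANOVA, dbRDA and variance
partitioning on the Bray-Curtis dissimilarity of a synthetic estuary.

PERMANOVA partitions distance-matrix variance among the design factors;
dbRDA regresses the Cailliez-corrected principal coordinates on z-scored
predictors (after VIF pruning) and reports Ezekiel-adjusted R^2; variance
partitioning splits that adjusted R^2 into unique and shared fractions.
"""
import pandas as pd

from ecoassembly import (
    EstuaryConfig,
    bray_curtis,
    db_rda,
    permanova,
    simulate_estuary_dataset,
    to_relative_abundance,
    variance_partition,
    vif_prune,
)

ds = simulate_estuary_dataset(EstuaryConfig(n_taxa=100, depth=2000, seed=9))
bc = bray_curtis(to_relative_abundance(ds.table))

res = permanova(bc, ds.metadata, ["station", "date", "fraction"], n_perm=199, seed=0)
print("PERMANOVA (sequential):")
print(res.table.round(3).to_string())

predictors = ds.metadata[["salinity", "temperature", "DIN", "phosphate", "SPM", "chla"]]
pruned = vif_prune(predictors, threshold=10)
print(f"\nVIF pruning removed: {[name for name, _ in pruned.removed]} (collinear with the rest)")

fit = db_rda(bc, predictors[pruned.retained], n_perm=199, seed=1)
print(f"dbRDA: R2 = {fit.r2:.2f}, adjusted R2 = {fit.adjusted_r2:.2f}, p = {fit.p_overall:.3f}")

vp = variance_partition(bc, predictors[pruned.retained],
                        {"salinity": ["salinity"], "season": ["temperature", "chla"]})
print("\nvariance partition of adjusted R2:")
print(vp.table().round(3).to_string())
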