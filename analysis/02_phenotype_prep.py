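"""Prepare plot-level phenotypes for association mapping: Papadakis
nearest-neighbour spatial adjustment, outlier removal on standardized
residuals (|z| > 3.5 treated as missing), then the REML mixed model
(env + block fixed; genotype and genotype-x-env random) for per-genotype
BLUPs, variance components and plot-basis heritability.

Reads results/panel/phenotypes.csv (run 01 first); writes
results/prep/blups.csv and variance_components.json.
"""

from pathlib import Path

from svrgwas import detect_outliers, fit_blup, nna_adjust
from svrgwas import io as sio

PANEL = Path("results/panel")
OUT = Path("results/prep")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = sio.read_phenotypes(PANEL / "phenotypes.csv")

    adjusted = nna_adjust(pheno, neighborhood_radius=1)
    adjusted, n_outliers = detect_outliers(adjusted, z_cut=3.5)
    res = fit_blup(adjusted)

    vc = res.variance_components
    blups = res.blups.to_frame("value")
    blups.index.name = "genotype"
    blups.to_csv(OUT / "blups.csv", float_format="%.8g")
    sio.write_json(
        {
            "sigma2_g": vc.sigma2_g,
            "sigma2_e": vc.sigma2_e,
            "sigma2_gxe": vc.sigma2_gxe,
            "mu": vc.mu,
            "h2": res.h2,
            "n_outliers_removed": n_outliers,
        },
        OUT / "variance_components.json",
    )

    print(f"{len(pheno)} plots over {pheno['env'].nunique()} environments")
    print(f"outliers set to missing: {n_outliers}")
    print(f"variance components: sigma2_G={vc.sigma2_g:.3f}, "
          f"sigma2_GxE={vc.sigma2_gxe:.3f}, sigma2_E={vc.sigma2_e:.3f}")
    print(f"plot-basis H2 = {res.h2:.3f}")
    print(f"wrote {OUT}/blups.csv and variance_components.json")


if __name__ == "__main__":
    main()
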