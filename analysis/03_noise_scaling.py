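#!/usr/bin/env python
"""Non-canonical noise scaling on a yeast-like synthetic proteome.

Generates a gene table with the yeast-like defaults (translation law
mu_p = 8.0*mu_m^2.1 with scatter, gamma-model noise with a floor), fits the
translation law, derives the parameter-free noise prediction and efficiency
law, then fits the empirical noise model under the canonical (a = 1) and
free-exponent hypotheses and runs the likelihood-ratio test.  Writes
results/noise_scaling_fits.json.
"""

import argparse
from pathlib import Path

from msgnoise import (
    GeneratorConfig,
    derive_efficiency_model,
    derive_noise_prediction,
    fit_noise_model,
    fit_translation_model,
    generate_gene_table,
    load_organism,
    test_canonical_scaling,
)
from msgnoise.io import write_fit_json

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-genes", type=int, default=3000)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    org = load_organism("yeast")
    cfg = GeneratorConfig(n_genes=args.n_genes, seed=args.seed)
    records, truth = generate_gene_table(cfg, org)

    tm = fit_translation_model(records)
    print(f"translation law: mu_p = {tm.amplitude:.2f} * mu_m^{tm.exponent:.3f} "
          f"(planted {cfg.translation_amplitude} * mu_m^{cfg.translation_exponent}, "
          f"n={tm.n})")

    noise_law = derive_noise_prediction(tm)
    eff_law = derive_efficiency_model(tm)
    print(f"derived noise law:      CV^2 = {noise_law.amplitude:.2f} * "
          f"mu_p^{noise_law.exponent:.3f}")
    print(f"derived efficiency law: eps  = {eff_law.amplitude:.2f} * "
          f"mu_m^{eff_law.exponent:.3f}")

    null = fit_noise_model(records, "null")
    alt = fit_noise_model(records, "alternative")
    p = test_canonical_scaling(null, alt)
    print(f"noise-model fit (free a): a = {alt.exponent:.3f} +/- {alt.exponent_se:.3f}, "
          f"b = {alt.amplitude:.2f}, c = {alt.floor:.4f} (n={alt.n})")
    print(f"canonical scaling (a = 1) rejected at p = {p:.3g}")
    print("\nWhen translation efficiency grows with expression (exponent ~2 in the"
          "\ntranslation law), noise scales like mu_p^-1/2 rather than mu_p^-1 —"
          "\nthe derived exponent above matches the free fit.")

    write_fit_json({
        "seed": args.seed,
        "n_genes": args.n_genes,
        "translation_fit": {"amplitude": tm.amplitude, "exponent": tm.exponent,
                            "exponent_se": tm.exponent_se, "n": tm.n},
        "derived_noise_law": {"amplitude": noise_law.amplitude,
                              "exponent": noise_law.exponent},
        "derived_efficiency_law": {"amplitude": eff_law.amplitude,
                                   "exponent": eff_law.exponent},
        "noise_fit_null": {"amplitude": null.amplitude, "floor": null.floor,
                           "loglik": null.loglik},
        "noise_fit_alternative": {"exponent": alt.exponent,
                                  "exponent_se": alt.exponent_se,
                                  "amplitude": alt.amplitude, "floor": alt.floor,
                                  "loglik": alt.loglik, "n": alt.n},
        "canonical_scaling_p_value": p,
    }, RESULTS / "noise_scaling_fits.json")


if __name__ == "__main__":
    main()
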