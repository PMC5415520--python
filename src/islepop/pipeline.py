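"""End-to-end orchestration of the analysis chain.

``run_all`` executes filter -> diversity -> differentiation -> drift
battery -> selection scan -> (optional) morphology on any input dataset,
writing one tidy TSV per stage plus a drift/selection summary, with a
single master seed fanned out per stage so adding a stage never perturbs
another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import (
    allele_frequencies, allelic_richness, bottleneck_test, coancestry_neb,
    compute_differentiation, candidate_frequency_contrast, drift_regression,
    f_is, filter_missing, genotypic_exact_test, heterozygosity, ho_he_ttest,
    hwe_test, jostd_envelope, ld_test, read_genepop, read_genotype_table,
    fdist_scan,
)
from .io import GenotypeDataset
from .morphology import anova_genotype_sex, age_correlation, read_morph_table

log = logging.getLogger("islepop")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults follow the analysis conventions of the study design: 999
    bootstraps for CIs, 2000 Monte-Carlo replications for exact tests, 999
    permutations for LD, 1000 iterations for the bottleneck test, alpha
    0.05 with Bonferroni correction.
    """

    genotypes: str = ""
    morphology: str | None = None
    candidate_locus: str = "IGF1"
    max_missing_loci: int = 2
    rarefaction_genes: int = 28
    n_boot: int = 999
    n_mc: int = 2000
    n_perm: int = 999
    n_iter: int = 1000
    n_sim_scan: int = 50000
    scan_conf: float = 0.95
    alpha: float = 0.05
    exact_alpha: float = 0.001
    mutation_model: str = "tpm"
    p_ss: float = 0.7
    variance: float = 30.0
    seed: int = 0
    outdir: str = "islepop_out"
    run_ld: bool = True
    run_scan: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# islepop config={config.config_hash()} seed={config.seed}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def load_genotypes(path: str | Path, candidate: str | None) -> GenotypeDataset:
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".csv", ".txt"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        return read_genotype_table(path, sep=sep, candidate_locus=candidate)
    return read_genepop(path, candidate_locus=candidate)


def run_all(config: RunConfig, data: GenotypeDataset | None = None) -> dict:
    """Execute the full analysis chain; returns the result bundle.

    Any stage failure aborts with the stage name and cause; outputs written
    so far are retained in ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        if data is None:
            data = load_genotypes(config.genotypes, config.candidate_locus)
        if config.candidate_locus in data.loci:
            data.candidate_locus = config.candidate_locus

        stage = "filter"
        data = filter_missing(data, config.max_missing_loci)
        results["data"] = data
        log.info("retained %d individuals in %d populations",
                 data.n_individuals, len(data.population_names()))

        stage = "diversity"
        div = heterozygosity(data)
        _write(div.per_locus, out / "heterozygosity.tsv", config)
        t, p = ho_he_ttest(div)
        ar = allelic_richness(data, config.rarefaction_genes, private=True)
        _write(ar.per_locus, out / "allelic_richness.tsv", config)
        fis = f_is(data, config.n_boot, _stage_seed(config.seed, "fis"))
        _write(fis, out / "fis.tsv", config)
        hwe = hwe_test(data, config.alpha)
        _write(hwe, out / "hwe.tsv", config)
        results.update(diversity=div, ar=ar, fis=fis, hwe=hwe,
                       ho_he_ttest={"t": t, "p": p})
        if config.run_ld:
            stage = "ld"
            ld = ld_test(data, config.n_perm, config.alpha,
                         _stage_seed(config.seed, "ld"))
            _write(ld, out / "ld.tsv", config)
            results["ld"] = ld

        stage = "differentiation"
        diffs = {}
        for statname in ("theta", "gst", "jostd"):
            res = compute_differentiation(
                data, statname, config.n_boot,
                _stage_seed(config.seed, f"diff-{statname}"),
            )
            diffs[statname] = res
            _write(res.per_locus, out / f"diff_{statname}_per_locus.tsv", config)
            res.matrix().to_csv(out / f"diff_{statname}_matrix.tsv", sep="\t")
        exact = genotypic_exact_test(
            data, config.n_mc, config.exact_alpha,
            _stage_seed(config.seed, "exact"),
        )
        _write(exact, out / "genotypic_exact.tsv", config)
        results.update(differentiation=diffs, exact=exact)

        stage = "drift"
        ne = coancestry_neb(data, _stage_seed(config.seed, "ne"))
        _write(ne.table, out / "ne.tsv", config)
        bott = bottleneck_test(
            data, config.mutation_model, config.p_ss, config.variance,
            config.n_iter, _stage_seed(config.seed, "bottleneck"),
        )
        _write(bott.per_population, out / "bottleneck.tsv", config)
        div_tables = {
            name: frame.rename(columns={col: "value"})[["population", "value"]]
            for name, col, frame in [
                ("H_O", "H_O", div.per_population),
                ("H_E", "H_E", div.per_population),
                ("AR", "AR", ar.per_population),
            ]
        }
        reg = drift_regression(
            {"theta": diffs["theta"], "jostd": diffs["jostd"]}, div_tables
        )
        _write(reg, out / "drift_regression.tsv", config)
        results.update(ne=ne, bottleneck=bott, regression=reg)

        stage = "selection"
        envelope = None
        contrast = None
        if data.candidate_locus is not None:
            cand = compute_differentiation(
                data, "jostd", n_boot=0, loci=[data.candidate_locus],
                marker_set="candidate",
            )
            envelope = jostd_envelope(diffs["jostd"], cand)
            _write(envelope.table, out / "jostd_envelope.tsv", config)
            freqs = allele_frequencies(data)
            pcontrast, ftab = candidate_frequency_contrast(
                freqs, data.candidate_locus, config.n_mc,
                _stage_seed(config.seed, "contrast"),
            )
            _write(pcontrast, out / "candidate_contrast.tsv", config)
            _write(ftab, out / "candidate_frequencies.tsv", config)
            contrast = pcontrast
        scan = None
        if config.run_scan:
            scan = fdist_scan(
                data, config.n_sim_scan, config.scan_conf,
                "smm", _stage_seed(config.seed, "scan"),
            )
            _write(scan.verdicts, out / "fdist_verdicts.tsv", config)
        results.update(envelope=envelope, contrast=contrast, scan=scan)

        if config.morphology:
            stage = "morphology"
            from .morphology import attach_genotypes
            morph = read_morph_table(config.morphology)
            if "genotype" not in morph.data.columns and data.candidate_locus:
                morph.data = attach_genotypes(
                    morph.data, data, data.candidate_locus
                )
            anova = anova_genotype_sex(morph, config.alpha)
            _write(anova, out / "morph_anova.tsv", config)
            corr = age_correlation(morph, config.alpha)
            _write(corr, out / "morph_age_correlation.tsv", config)
            results.update(anova=anova, age_correlation=corr)

        stage = "summary"
        summary = _summarise(results, config)
        (out / "summary.txt").write_text(summary)
        results["summary"] = summary
        return results
    except Exception as exc:  # re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _summarise(results: dict, config: RunConfig) -> str:
    lines = [
        f"islepop run (config {config.config_hash()}, seed {config.seed})",
        "",
        "Drift evidence:",
    ]
    ne = results.get("ne")
    if ne is not None:
        for _, r in ne.table.iterrows():
            v = "infinite" if r["infinite"] else f"{r['N_eb']:.1f}"
            lines.append(f"  N_eb[{r['population']}] = {v}")
    bott = results.get("bottleneck")
    if bott is not None:
        for _, r in bott.per_population.iterrows():
            lines.append(
                f"  bottleneck p_excess[{r['population']}] = {r['p_excess']:.4g}"
                f" ({int(r['n_loci'])} loci)"
            )
    reg = results.get("regression")
    if reg is not None:
        for _, r in reg.iterrows():
            lines.append(
                f"  slope {r['diff_metric']}~{r['diversity_metric']}:"
                f" {r['slope']:.3g} (R2={r['r2']:.2f}, p={r['p']:.3g})"
            )
    lines.append("")
    lines.append("Selection evidence:")
    env = results.get("envelope")
    if env is not None:
        for _, r in env.table.iterrows():
            lines.append(
                f"  D[{r['pop1']}-{r['pop2']}]: candidate {r['D_candidate']:.3f}"
                f" vs neutral {r['D_neutral_mean']:.3f}+/-{r['sem']:.3f}"
                f" -> {r['classification']}"
            )
    scan = results.get("scan")
    if scan is not None:
        flagged = scan.verdicts[scan.verdicts["verdict"] != "neutral"]
        if len(flagged):
            for _, r in flagged.iterrows():
                lines.append(f"  scan: {r['locus']} -> {r['verdict']}")
        else:
            lines.append("  scan: no outlier loci flagged")
    return "\n".join(lines) + "\n"
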