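"""End-to-end analysis pipeline with a reproducibility manifest.

Stage order mirrors a standard control-region survey: score sequences
against the reference, classify haplogroups, summarise diversity per
population and per pooled region, run neutrality tests, estimate
population structure (pairwise PhiST, AMOVA, PCoA), and build the
median-joining network. Every stage seed derives from one master seed
via numpy's SeedSequence spawning; the manifest records input/output
checksums so a re-run under the same configuration is byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import (
    classify_sites,
    collapse_haplotypes,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_differences,
    write_haplotype_fasta,
)
from .haplogroups import (
    classify,
    default_motif_tree,
    haplogroup_frequencies,
    load_motif_tree,
    write_classifications_tsv,
)
from .network import add_median_vectors, write_edge_tsv, write_graphml, write_nexus_network
from .neutrality import neutrality_pvalues
from .reference import default_reference, load_reference
from .seqio import anchor_to_reference, call_substitutions, read_fasta, write_variants_tsv
from .structure import amova, pairwise_fst, pcoa_from_fst

logger = logging.getLogger(__name__)

ALL_STAGES = ("score", "classify", "diversity", "neutrality", "structure", "network")


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    out_dir: str
    reference: str | None = None  # None -> bundled synthetic reference
    motif_tree: str | None = None  # None -> bundled CDV scheme
    layout: dict[str, list[str]] | None = None  # AMOVA grouping
    fst_permutations: int = 10000
    amova_permutations: int = 1000
    neutrality_reps: int = 1000
    epsilon: int = 0
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    already_aligned: bool = False  # skip pairwise alignment (in-frame input)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt(x: float) -> str:
    return "NA" if x != x else f"{x:.10g}"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute enabled stages; return (and write) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(ALL_STAGES, master.spawn(len(ALL_STAGES)))
    }
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "parameters": {
            "fst_permutations": cfg.fst_permutations,
            "amova_permutations": cfg.amova_permutations,
            "neutrality_reps": cfg.neutrality_reps,
            "epsilon": cfg.epsilon,
            "stages": list(cfg.stages),
        },
        "inputs": {},
        "outputs": {},
    }
    for key, p in (("fasta", cfg.fasta), ("popmap", cfg.popmap)):
        manifest["inputs"][key] = _sha256(Path(p))

    ref = load_reference(cfg.reference) if cfg.reference else default_reference()
    tree = load_motif_tree(cfg.motif_tree) if cfg.motif_tree else default_motif_tree()
    records = read_fasta(cfg.fasta, cfg.popmap)
    popmap = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "population": [r.population for r in records],
            "region": [r.region for r in records],
        }
    )

    outputs: dict[str, Path] = {}

    # --- score ---------------------------------------------------------
    from .seqio import AlignedSequence

    if cfg.already_aligned:
        alns = [AlignedSequence(sample_id=r.sample_id, states=r.raw_seq) for r in records]
    else:
        alns = [anchor_to_reference(r, ref) for r in records]
    variant_sets = [call_substitutions(a, ref) for a in alns]
    if "score" in cfg.stages:
        p = out / "variants.tsv"
        write_variants_tsv(variant_sets, p)
        outputs["variants"] = p

    # --- classify ------------------------------------------------------
    results = [classify(vs, tree) for vs in variant_sets]
    if "classify" in cfg.stages:
        p = out / "haplogroups.tsv"
        write_classifications_tsv(results, p)
        outputs["haplogroups"] = p
        freq = haplogroup_frequencies(results, popmap)
        p = out / "haplogroup_frequencies.tsv"
        freq.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs["haplogroup_frequencies"] = p

    # --- diversity + neutrality ---------------------------------------
    if "diversity" in cfg.stages or "neutrality" in cfg.stages:
        rows = []
        by_pop = {r.sample_id: r.population for r in records}
        by_region = {r.sample_id: r.region for r in records}
        groupings = [("population", by_pop)]
        if any(by_region.values()):
            groupings.append(("region", by_region))
        for level, mapping in groupings:
            for value in dict.fromkeys(mapping.values()):
                subset = [a for a in alns if mapping[a.sample_id] == value]
                if len(subset) < 4:
                    logger.warning("%s %s: n=%d < 4, skipped", level, value, len(subset))
                    continue
                part = collapse_haplotypes(subset)
                sites = classify_sites(subset)
                hd, hd_se = haplotype_diversity(part)
                pi, pi_se = nucleotide_diversity(subset)
                d2, L_eff = pairwise_differences(subset)
                n = len(subset)
                pi_total = float(d2[np.triu_indices(n, k=1)].sum()) / (n * (n - 1) / 2)
                row = {
                    "level": level,
                    "group": value,
                    "N": n,
                    "Ht": part.Ht,
                    "S": sites.S,
                    "Hd": hd,
                    "Hd_se": hd_se,
                    "pi": pi,
                    "pi_se": pi_se,
                }
                if "neutrality" in cfg.stages and sites.S > 0 and pi_total > 0:
                    nres = neutrality_pvalues(
                        n,
                        sites.S,
                        pi_total,
                        part.Ht,
                        n_reps=cfg.neutrality_reps,
                        seed=stage_seeds["neutrality"],
                    )
                    row.update(
                        {
                            "tajimas_D": nres.D,
                            "p_D": nres.p_D,
                            "fus_Fs": nres.Fs,
                            "p_Fs": nres.p_Fs,
                            "n_reps": nres.n_reps,
                            "stage_seed": stage_seeds["neutrality"],
                        }
                    )
                rows.append(row)
        table = pd.DataFrame(rows)
        p = out / "diversity.tsv"
        # 3-decimal presentation mirror plus a full-precision table
        table_rounded = table.copy()
        for col in ("Hd", "pi"):
            if col in table_rounded:
                table_rounded[col] = table_rounded[col].round(3)
        table_rounded.to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs["diversity"] = p
        p_full = out / "diversity_full.tsv"
        table.to_csv(p_full, sep="\t", index=False, float_format="%.12g")
        outputs["diversity_full"] = p_full

    # --- structure -----------------------------------------------------
    if "structure" in cfg.stages:
        fst = pairwise_fst(
            alns, popmap, n_perm=cfg.fst_permutations, seed=stage_seeds["structure"]
        )
        p = out / "fst_matrix.tsv"
        with open(p, "w") as fh:
            fh.write("population\t" + "\t".join(fst.populations) + "\n")
            for i, pop in enumerate(fst.populations):
                cells = []
                for j in range(len(fst.populations)):
                    if j < i:
                        cells.append(_fmt(fst.matrix[i, j]))  # lower: PhiST
                    elif j > i:
                        cells.append(_fmt(fst.p_matrix[i, j]))  # upper: p
                    else:
                        cells.append("0")
                fh.write(pop + "\t" + "\t".join(cells) + "\n")
        outputs["fst_matrix"] = p

        am = amova(
            alns,
            popmap,
            layout=cfg.layout,
            n_perm=cfg.amova_permutations,
            seed=stage_seeds["structure"],
        )
        p = out / "amova.tsv"
        with open(p, "w") as fh:
            fh.write("component\tdf\tSS\tsigma2\tpercent\tphi\tp_value\n")
            labels = ("among_groups", "among_populations_within_groups", "within_populations")
            phis = (am.phi_ct, am.phi_sc, am.phi_st)
            ps = (am.p_phi_ct, am.p_phi_sc, am.p_phi_st)
            for k in range(3):
                fh.write(
                    f"{labels[k]}\t{am.df[k]}\t{_fmt(am.ss[k])}\t{_fmt(am.sigma2[k])}\t"
                    f"{_fmt(am.percentages[k])}\t{_fmt(phis[k])}\t{_fmt(ps[k])}\n"
                )
        outputs["amova"] = p

        if len(fst.populations) >= 3:
            pcoa = pcoa_from_fst(fst)
            p = out / "pcoa.tsv"
            with open(p, "w") as fh:
                naxes = pcoa.coordinates.shape[1]
                fh.write("population\t" + "\t".join(f"axis{k + 1}" for k in range(naxes)) + "\n")
                for i, lab in enumerate(pcoa.labels):
                    fh.write(lab + "\t" + "\t".join(_fmt(x) for x in pcoa.coordinates[i]) + "\n")
                fh.write(
                    "percent_variation\t"
                    + "\t".join(_fmt(x) for x in pcoa.percent_variation)
                    + "\n"
                )
            outputs["pcoa"] = p

    # --- network ---------------------------------------------------------
    if "network" in cfg.stages:
        part = collapse_haplotypes(alns)
        hap_fasta = out / "haplotypes.fasta"
        write_haplotype_fasta(part, hap_fasta)
        outputs["haplotypes"] = hap_fasta
        # restrict node states to variable sites for compact networks
        states = part.representative_states
        varmask = [
            k for k in range(len(states[0])) if len({s[k] for s in states}) > 1
        ]
        var_states = ["".join(s[k] for k in varmask) for s in states]
        var_positions = tuple(int(part.included_sites[k]) for k in varmask)
        pop_counts: dict[str, dict[str, int]] = {}
        pop_of = dict(zip(popmap["sample_id"], popmap["population"]))
        for hid, members in zip(part.haplotype_ids, part.members):
            tally: dict[str, int] = {}
            for sid in members:
                tally[pop_of[sid]] = tally.get(pop_of[sid], 0) + 1
            pop_counts[hid] = tally
        from .diversity import HaplotypePartition

        var_part = HaplotypePartition(
            haplotype_ids=part.haplotype_ids,
            representative_states=var_states,
            members=part.members,
            included_sites=np.array(var_positions, dtype=int),
        )
        net = add_median_vectors(
            var_part, epsilon=cfg.epsilon, populations=pop_counts,
            variable_positions=var_positions,
        )
        p = out / "network.nex"
        write_nexus_network(net, p)
        outputs["network_nexus"] = p
        p = out / "network.graphml"
        write_graphml(net, p)
        outputs["network_graphml"] = p
        p = out / "network_edges.tsv"
        write_edge_tsv(net, p)
        outputs["network_edges"] = p

    manifest["outputs"] = {k: _sha256(v) for k, v in sorted(outputs.items())}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
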