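"""Final bundle: map genes into the informative regions, flag candidate-list
hits, and emit the deterministic report tables in one place.

This is the same end-to-end path as the single-command
``poolcnv.pipeline.run_all``; running it from the stage checkpoints or from
scratch gives identical outputs (same seed, same config)."""

from poolcnv.pipeline import run_all

from study import OUT, pipeline_config


def main() -> None:
    res = run_all(pipeline_config())
    print(f"report bundle -> {OUT / 'pipeline'}")
    for key, path in sorted(res.report_paths.items()):
        print(f"  {key}: {path.name}")
    if res.gene_map is not None:
        flagged = sorted(res.gene_map.flagged_genes())
        print(f"genes mapped into informative regions: "
              f"{sorted(res.gene_map.unique_genes)}")
        print(f"candidate-list hits: {flagged}")


if __name__ == "__main__":
    main()
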