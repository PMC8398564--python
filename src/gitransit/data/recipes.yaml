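# Shipped chemistry constants and biorelevant fluid recipes.
#
# Species entries describe how each named solute enters the charge balance:
#   cation_equiv  strong-cation (Na+) equivalents carried per mM of the solute
#   anion_equiv   strong-anion equivalents carried per mM (fully dissociated)
#   chloride      whether the strong anion is chloride (relevant for common-ion
#                 solubility caps of weak-base hydrochlorides)
#   pkas          successive acid dissociation constants of the fully
#                 protonated form; a species with j protons removed carries
#                 charge -j relative to that form.
#
# Notes on the defaults:
#   - sodium taurocholate is treated as a fully dissociated 1:1 sodium salt
#     (electroneutral spectator); lecithin and d-glucose are uncharged.
#   - carbonate uses only the first dissociation (closed system; the second
#     pKa of 10.33 is irrelevant below pH 9).
#   - HEPES is zwitterionic; only the piperazine dissociation near 7.55
#     matters, modelled as a 0/-1 monoprotic acid.
#   - the HBSS carrier salts are folded into one electroneutral background
#     species; HBSS's own glucose (19.45 mM) is already included in the
#     d_glucose total of the intestinal recipe (5.55 + 19.45 = 25 mM).
species:
  sodium_taurocholate: {cation_equiv: 1, anion_equiv: 1, chloride: false, pkas: []}
  lecithin:            {cation_equiv: 0, anion_equiv: 0, chloride: false, pkas: []}
  nacl:                {cation_equiv: 1, anion_equiv: 1, chloride: true,  pkas: []}
  na2hpo4:             {cation_equiv: 2, anion_equiv: 0, chloride: false, pkas: [2.15, 7.20, 12.35]}
  citric_acid:         {cation_equiv: 0, anion_equiv: 0, chloride: false, pkas: [3.13, 4.76, 6.40]}
  nahco3:              {cation_equiv: 1, anion_equiv: 0, chloride: false, pkas: [6.35]}
  d_glucose:           {cation_equiv: 0, anion_equiv: 0, chloride: false, pkas: []}
  hepes:               {cation_equiv: 0, anion_equiv: 0, chloride: false, pkas: [7.55]}
  hbss_background:     {cation_equiv: 0, anion_equiv: 0, chloride: false, pkas: []}

# Total analytical concentrations in mM.
recipes:
  fassgf:
    label: "FaSSGF (fasted-state simulated gastric fluid)"
    species:
      sodium_taurocholate: 0.08
      lecithin: 0.02
      nacl: 34.2
      na2hpo4: 20.0
      citric_acid: 10.0
  fassif:
    label: "FaSSIF (fasted-state simulated intestinal fluid, HBSS-based)"
    species:
      sodium_taurocholate: 3.0
      lecithin: 0.75
      nacl: 13.7
      na2hpo4: 20.0
      citric_acid: 10.0
      nahco3: 4.17
      d_glucose: 25.0
      hepes: 10.0
      hbss_background: 140.0
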