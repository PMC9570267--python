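{
 "activities.csv": "c8ca6adf821a74d4fd515eec692dd33dafbc8ca6d424acec099f92817f3deaf3",
 "bondlengths_tu.csv": "3345d563c8c008dc2beb1aa1ed05221984790b3b2b84fe079f09784d3af6d179",
 "docking_alpha.csv": "fbc63c67d1b19a57977265715f0616e1dafb06623b77f6695fc0e2329ff75c4b",
 "docking_beta.csv": "52758b2b19c05c44c1b07590cc4e47c4b4245ed71c8283f73db459212feb86ea",
 "energies_dipoles.csv": "0f96395844b61156c7a7e6e8421346f13020bd825df29f75beb1cedc5aa349f1",
 "physchem.csv": "977019af770c8049b07ae85b6cb0c12bac787ccfc2e7425ad0834eefad3db1bb",
 "reactivity_inputs.csv": "845396d572de807630edb8906b2423c168e210011060290da3e34c3997314259",
 "sar_properties.csv": "98f146c8b9e9462b68a38eb4d7e6f8b9adf1703fe51a369a188bc243813cb04f"
}
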