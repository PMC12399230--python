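# Default code sets and drug dictionary.  Users substitute their own code
# lists (e.g. a full guideline regimen list or local surgery/radiotherapy
# procedure codes) by editing a copy of this file and loading it with
# CodeConfig.from_toml().  Code matching is by dot-stripped string prefix.

lc_diagnosis_codes = ["1622", "1623", "1624", "1625", "1628", "1629", "C34"]
metastatic_codes = ["196", "197", "198", "2097", "C77", "C78", "C79", "C7B"]
brain_metastasis_codes = ["1983", "C793"]
sclc_agents = ["etoposide", "irinotecan", "topotecan"]
egfr_tki_agents = ["gefitinib", "erlotinib", "afatinib", "osimertinib", "dacomitinib"]
lc_surgery_procedure_codes = ["32440", "32480", "32505"]
radiotherapy_procedure_codes = ["774", "7731"]
admin_procedure_codes = ["chemo_admin", "96413", "96415"]
osimertinib_approval_date = "2018-04-18"

[drug_dictionary]
gefitinib = "egfr_tki"
erlotinib = "egfr_tki"
afatinib = "egfr_tki"
osimertinib = "egfr_tki"
dacomitinib = "egfr_tki"
carboplatin = "platinum"
cisplatin = "platinum"
pemetrexed = "nonplatinum_chemo"
paclitaxel = "nonplatinum_chemo"
docetaxel = "nonplatinum_chemo"
gemcitabine = "nonplatinum_chemo"
etoposide = "nonplatinum_chemo"
irinotecan = "nonplatinum_chemo"
topotecan = "nonplatinum_chemo"
pembrolizumab = "immunotherapy"
nivolumab = "immunotherapy"
atezolizumab = "immunotherapy"
durvalumab = "immunotherapy"
ipilimumab = "immunotherapy"
amivantamab = "other_antineoplastic"
oxycodone = "supportive:pain"
morphine = "supportive:pain"
hydrocodone_acetaminophen = "supportive:pain"
fentanyl = "supportive:pain"
albuterol = "supportive:respiratory"
oxygen_supply = "supportive:respiratory"
filgrastim = "supportive:gcsf"
pegfilgrastim = "supportive:gcsf"
sargramostim = "supportive:gcsf"
epoetin_alfa = "supportive:esa"
darbepoetin_alfa = "supportive:esa"
dexamethasone = "supportive:corticosteroid"
prednisone = "supportive:corticosteroid"
methylprednisolone = "supportive:corticosteroid"
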