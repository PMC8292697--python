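{
  "version": "rtqa starter lexicon v1 (prostate + lung OARs and targets)",
  "entries": [
    {"tg263_name": "Bladder", "category": "OAR", "synonyms": ["urinary bladder", "blad", "vessie"]},
    {"tg263_name": "Rectum", "category": "OAR", "synonyms": ["rect", "rectal wall"]},
    {"tg263_name": "Femur_Head_L", "category": "OAR", "synonyms": ["left femoral head", "l femur", "femhead lt"]},
    {"tg263_name": "Femur_Head_R", "category": "OAR", "synonyms": ["right femoral head", "r femur", "femhead rt"]},
    {"tg263_name": "PenileBulb", "category": "OAR", "synonyms": ["penile bulb", "bulb"]},
    {"tg263_name": "Urethra", "category": "OAR", "synonyms": []},
    {"tg263_name": "Bowel_Small", "category": "OAR", "synonyms": ["small bowel", "small intestine"]},
    {"tg263_name": "Bowel_Large", "category": "OAR", "synonyms": ["large bowel", "colon"]},
    {"tg263_name": "Sigmoid", "category": "OAR", "synonyms": ["sigmoid colon"]},
    {"tg263_name": "Prostate", "category": "TARGET", "synonyms": ["prostate gland"]},
    {"tg263_name": "SeminalVes", "category": "TARGET", "synonyms": ["seminal vesicles", "sv"]},
    {"tg263_name": "LN_Pelvic", "category": "TARGET", "synonyms": ["pelvic nodes", "pelvic lymph nodes"]},
    {"tg263_name": "Lung_L", "category": "OAR", "synonyms": ["left lung", "l lung", "lung lt"]},
    {"tg263_name": "Lung_R", "category": "OAR", "synonyms": ["right lung", "r lung", "lung rt"]},
    {"tg263_name": "Lungs", "category": "OAR", "synonyms": ["both lungs", "total lung", "lungs-gtv"]},
    {"tg263_name": "Heart", "category": "OAR", "synonyms": ["cardiac", "coeur"]},
    {"tg263_name": "Esophagus", "category": "OAR", "synonyms": ["oesophagus", "esoph"]},
    {"tg263_name": "SpinalCord", "category": "OAR", "synonyms": ["spinal cord", "cord", "sc"]},
    {"tg263_name": "SpinalCanal", "category": "OAR", "synonyms": ["spinal canal", "canal"]},
    {"tg263_name": "BrachialPlex_L", "category": "OAR", "synonyms": ["left brachial plexus", "l brachial plexus"]},
    {"tg263_name": "BrachialPlex_R", "category": "OAR", "synonyms": ["right brachial plexus", "r brachial plexus"]},
    {"tg263_name": "GreatVes", "category": "OAR", "synonyms": ["great vessels", "aorta"]},
    {"tg263_name": "Trachea", "category": "OAR", "synonyms": []},
    {"tg263_name": "Bronchus_Main", "category": "OAR", "synonyms": ["proximal bronchial tree", "main bronchus"]},
    {"tg263_name": "ChestWall", "category": "OAR", "synonyms": ["chest wall", "thoracic wall"]},
    {"tg263_name": "Liver", "category": "OAR", "synonyms": ["hepatic"]},
    {"tg263_name": "Kidney_L", "category": "OAR", "synonyms": ["left kidney", "l kidney"]},
    {"tg263_name": "Kidney_R", "category": "OAR", "synonyms": ["right kidney", "r kidney"]},
    {"tg263_name": "Stomach", "category": "OAR", "synonyms": ["gastric"]},
    {"tg263_name": "CaudaEquina", "category": "OAR", "synonyms": ["cauda equina"]},
    {"tg263_name": "Skin", "category": "OAR", "synonyms": ["body surface"]},
    {"tg263_name": "Body", "category": "OAR", "synonyms": ["external", "patient outline", "skin outline"]},
    {"tg263_name": "GTV", "category": "TARGET", "synonyms": ["gross tumor volume", "gross target volume"]},
    {"tg263_name": "CTV", "category": "TARGET", "synonyms": ["clinical target volume"]},
    {"tg263_name": "PTV", "category": "TARGET", "synonyms": ["planning target volume"]},
    {"tg263_name": "GTV_Primary", "category": "TARGET", "synonyms": ["gtv p", "primary gtv"]},
    {"tg263_name": "GTV_Nodal", "category": "TARGET", "synonyms": ["gtv n", "nodal gtv"]},
    {"tg263_name": "CTV_High", "category": "TARGET", "synonyms": ["ctv boost", "high dose ctv"]},
    {"tg263_name": "PTV_High", "category": "TARGET", "synonyms": ["ptv boost", "high dose ptv"]},
    {"tg263_name": "PTV_Low", "category": "TARGET", "synonyms": ["ptv elective", "low dose ptv"]}
  ]
}
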