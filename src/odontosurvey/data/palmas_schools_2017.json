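{
  "description": "Municipal schools of Palmas-TO offering the 9th grade of elementary school in 2017, with health territory, total enrollment and 9th-grade enrollment (Municipal Secretary of Education figures).",
  "year": 2017,
  "printed_totals": {"enrollment_total": 16321, "enrollment_grade9": 2014},
  "schools": [
    {"id": "S01", "territory": "Krahô", "name": "Escola Municipal Antonio Carlos Jobim", "enrollment_total": 599, "enrollment_grade9": 99},
    {"id": "S02", "territory": "Xambioá", "name": "Escola Municipal Antonio G. De Carvalho Filho", "enrollment_total": 618, "enrollment_grade9": 70},
    {"id": "S03", "territory": "Apinajé", "name": "Escola Municipal Anne Frank", "enrollment_total": 838, "enrollment_grade9": 80},
    {"id": "S04", "territory": "Xambioá", "name": "Escola Municipal Darcy Ribeiro", "enrollment_total": 476, "enrollment_grade9": 117},
    {"id": "S05", "territory": "Apinajé", "name": "Escola Municipal Henrique Talone Pinheiro", "enrollment_total": 794, "enrollment_grade9": 80},
    {"id": "S06", "territory": "Xambioá", "name": "Escola Municipal de Tempo Integral Vinícius de Moraes", "enrollment_total": 483, "enrollment_grade9": 81},
    {"id": "S07", "territory": "Kanela", "name": "Escola Municipal Beatriz Rodrigues da Silva", "enrollment_total": 897, "enrollment_grade9": 157},
    {"id": "S08", "territory": "Kanela", "name": "Escola Municipal Mestre Pacifico S. Campos", "enrollment_total": 431, "enrollment_grade9": 74},
    {"id": "S09", "territory": "Kanela", "name": "Escola Municipal Luiz Gonzaga", "enrollment_total": 264, "enrollment_grade9": 65},
    {"id": "S10", "territory": "Kanela", "name": "Escola Municipal Tempo Integral Padre Josimo M. Tavares", "enrollment_total": 1087, "enrollment_grade9": 116},
    {"id": "S11", "territory": "Apinajé", "name": "Escola Municipal Tempo Integral Daniel Batista", "enrollment_total": 386, "enrollment_grade9": 29},
    {"id": "S12", "territory": "Apinajé", "name": "Escola Municipal Tempo Integral Monsenhor Pedro P. Piagem", "enrollment_total": 466, "enrollment_grade9": 35},
    {"id": "S13", "territory": "Javaé", "name": "Escola Municipal Jorge Amado", "enrollment_total": 568, "enrollment_grade9": 159},
    {"id": "S14", "territory": "Javaé", "name": "Escola Municipal Maria Rosa De Castro Sales", "enrollment_total": 703, "enrollment_grade9": 79},
    {"id": "S15", "territory": "Krahô", "name": "Escola Municipal Professora Savia F. Jacome", "enrollment_total": 558, "enrollment_grade9": 71},
    {"id": "S16", "territory": "Javaé", "name": "Escola Municipal de Tempo Integral Caroline C. C. Da Silva", "enrollment_total": 1187, "enrollment_grade9": 72},
    {"id": "S17", "territory": "Karajá", "name": "Escola Municipal Aurelio Buarque De Holanda", "enrollment_total": 776, "enrollment_grade9": 115},
    {"id": "S18", "territory": "Xerente", "name": "Escola Municipal Maria Julia Amorim Rodrigues", "enrollment_total": 694, "enrollment_grade9": 176},
    {"id": "S19", "territory": "Karajá", "name": "Escola Municipal Thiago Barbosa", "enrollment_total": 896, "enrollment_grade9": 104},
    {"id": "S20", "territory": "Xerente", "name": "Escola Municipal de Tempo Integral Euridice F. De Mello", "enrollment_total": 1088, "enrollment_grade9": 68},
    {"id": "S21", "territory": "Xerente", "name": "Escola Municipal de Tempo Integral Margarida Gonçalves", "enrollment_total": 1028, "enrollment_grade9": 62},
    {"id": "S22", "territory": "Pankararu", "name": "Escola Municipal Crispim Pereira Alencar", "enrollment_total": 565, "enrollment_grade9": 33},
    {"id": "S23", "territory": "Apinajé", "name": "Escola Municipal de Tempo Integral Aprigio T. De Matos", "enrollment_total": 235, "enrollment_grade9": 15},
    {"id": "S24", "territory": "Pankararu", "name": "Escola Municipal de Tempo Integral Joao Beltrao", "enrollment_total": 217, "enrollment_grade9": 21},
    {"id": "S25", "territory": "Pankararu", "name": "Escola Municipal de Tempo Integral Luiz Nunes De Oliveira", "enrollment_total": 249, "enrollment_grade9": 22},
    {"id": "S26", "territory": "Pankararu", "name": "Escola Municipal de Tempo Integral Sueli Pereira A. Reche", "enrollment_total": 218, "enrollment_grade9": 14}
  ]
}
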