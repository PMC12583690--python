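code,label,service_category
A1,Meal delivery service,life
A2,Indoor cleaning service,life
A3,Item storage solution,life
A4,Maintenance service,life
A5,Heavy lifting service,life
A6,Indoor anti-slip and anti-fall service,life
A7,Pet walking service,life
A8,Daily necessities purchasing service,life
A9,Sewing and repair service,life
A10,Electronic product use training,life
A11,Attire matching guidance service,life
B1,Wearable emergency call device,intelligent
B2,Intelligent reminders for going out,intelligent
B3,Intelligent chat terminal system,intelligent
B4,Household robot,intelligent
B5,Smart security door lock,intelligent
B6,Surveillance equipment system,intelligent
C1,Diet and health training program,health
C2,High-end nutritious meals,health
C3,Regular physical examination service,health
C4,Medication purchasing service,health
C5,Home haircut service,health
C6,Assistance with hair washing or bathing,health
C7,Rehabilitation training and nursing care,health
C8,Wheelchair-assisted walks service,health
C9,Online medical consultation service,health
C10,Tuina massage service,health
C11,Preparation of chinese medicine,health
D1,Legal consultation service,security
D2,Anti-fraud publicity campaign,security
D3,Service personnel complaints handling,security
D4,Emergency call response system,security
D5,Service personnel reliability audit,security
D6,3-party indoor surveillance system,security
D7,Service process recording,security
D8,Indoor property registration service,security
D9,Regular trauma examination service,security
D10,Refusal to accept inheritance service,security
E1,Chat and social activities,spiritual
E2,Psychological counseling service,spiritual
E3,Musical activities,spiritual
E4,Hobby-based activities,spiritual
E5,Board and card games,spiritual
E6,Senior social events,spiritual
E7,Square dancing,spiritual
E8,Traveling,spiritual
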